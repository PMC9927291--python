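"""Variance partitioning of a per-genome scalar by taxonomy rank.

At a given rank, the total sum of squares of the trait (``SS_T``) splits
into a within-taxon part (``SS_W``, the sum over taxa of squared deviations
from the taxon mean) and a between-taxon part.  ``1 - SS_W/SS_T`` is the
fraction of variance the rank's grouping accounts for.  Because NCBI-style
ranks are nested, ``SS_W`` can only shrink as labels get finer, so the
explained fraction is non-decreasing from phylum to species.

Group comparisons use the two-sided Wilcoxon rank-sum test with Bonferroni
adjustment across the batch of comparisons run together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RANKS = ("phylum", "class", "order", "family", "genus", "species")

__all__ = ["RANKS", "TaxonomyTable", "VarianceProfile", "variance_components",
           "variance_profile", "group_compare", "compare_batch"]


@dataclass
class TaxonomyTable:
    """genome_id -> ordered rank labels (coarse to fine)."""

    ranks: tuple[str, ...]
    labels: dict[str, tuple[str, ...]]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, id_col: str = "genome_id",
                   ranks: tuple[str, ...] = RANKS) -> "TaxonomyTable":
        present = tuple(r for r in ranks if r in df.columns)
        labels = {row[id_col]: tuple(row[r] for r in present)
                  for _, row in df.iterrows()}
        return cls(ranks=present, labels=labels)

    def is_nested(self) -> bool:
        """True if sharing a label at rank r implies sharing all coarser ranks."""
        for r in range(1, len(self.ranks)):
            parent_of: dict[str, tuple] = {}
            for lab in self.labels.values():
                prev = parent_of.setdefault(lab[r], lab[:r])
                if prev != lab[:r]:
                    return False
        return True


@dataclass
class VarianceProfile:
    """Per-rank variance decomposition of one trait."""

    table: pd.DataFrame  # rank, n, n_groups, ss_total, ss_within, explained, unexplained


def variance_components(values, labels) -> tuple[float, float, float, float]:
    """(SS_T, SS_W, explained, unexplained) for one grouping.

    ``SS_T = sum (x - grand mean)^2``; ``SS_W = sum over groups of
    sum (x - group mean)^2``; explained ``= 1 - SS_W/SS_T``.  Constant
    values (SS_T = 0) leave the fractions undefined (NaN).
    """
    x = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(x) != len(labels):
        raise ValueError("values and labels must align")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    ss_t = float(np.sum((x - x.mean()) ** 2))
    ss_w = 0.0
    for lab in pd.unique(labels):
        grp = x[labels == lab]
        ss_w += float(np.sum((grp - grp.mean()) ** 2))
    if ss_t == 0.0:
        return ss_t, ss_w, float("nan"), float("nan")
    unexplained = ss_w / ss_t
    return ss_t, ss_w, 1.0 - unexplained, unexplained


def variance_profile(values: dict[str, float], taxonomy: TaxonomyTable
                     ) -> VarianceProfile:
    """Apply :func:`variance_components` at every rank, coarse to fine.

    Genomes lacking a label at a rank are excluded at that rank only.
    A non-nested taxonomy is allowed but breaks the monotonicity guarantee
    (warned).
    """
    if not taxonomy.is_nested():
        logger.warning("taxonomy labels are not nested; the explained "
                       "fraction need not be monotone across ranks")
    rows = []
    for r, rank in enumerate(taxonomy.ranks):
        ids = [g for g in values
               if g in taxonomy.labels and _has_label(taxonomy.labels[g], r)]
        n_dropped = len(values) - len(ids)
        if n_dropped:
            logger.warning("rank %s: dropped %d genomes without labels",
                           rank, n_dropped)
        x = [values[g] for g in ids]
        labs = [taxonomy.labels[g][r] for g in ids]
        ss_t, ss_w, expl, unexpl = variance_components(x, labs)
        rows.append({"rank": rank, "n": len(ids),
                     "n_groups": len(set(labs)), "ss_total": ss_t,
                     "ss_within": ss_w, "explained": expl,
                     "unexplained": unexpl})
    return VarianceProfile(table=pd.DataFrame(rows))


def _has_label(labels: tuple, r: int) -> bool:
    return r < len(labels) and labels[r] is not None and labels[r] == labels[r] \
        and labels[r] != ""


def group_compare(values_a, values_b, n_tests: int = 1
                  ) -> tuple[float, float, float]:
    """Two-sided Wilcoxon rank-sum test: (W, p, Bonferroni-adjusted p).

    ``W`` is the rank sum of the first sample.  With both groups of size
    <= 12 and no ties across samples the p-value comes from exhaustive
    enumeration of rank assignments; otherwise the normal approximation
    with continuity and tie correction is used.
    ``p_adjusted = min(1, n_tests * p)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 12 and len(b) <= 12 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    w = float(res.statistic) + len(a) * (len(a) + 1) / 2.0  # U -> rank sum
    p = float(res.pvalue)
    return w, p, min(1.0, n_tests * p)


def compare_batch(groups: dict[str, np.ndarray],
                  pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Run a batch of pairwise comparisons with a shared Bonferroni family.

    The multiplicity m equals the number of comparisons in the batch and is
    recorded in the output.
    """
    if pairs is None:
        names = sorted(groups)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    m = len(pairs)
    rows = []
    for ga, gb in pairs:
        w, p, p_adj = group_compare(groups[ga], groups[gb], n_tests=m)
        rows.append({"group_a": ga, "group_b": gb,
                     "n_a": len(groups[ga]), "n_b": len(groups[gb]),
                     "W": w, "p": p, "p_adj": p_adj, "m": m})
    return pd.DataFrame(rows)
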