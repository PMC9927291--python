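"""Statistics on the genome x KEGG-ortholog (KO) presence/absence matrix.

The functional inventory of a genome set is summarized as a binary matrix
(1 = the KO was detected in the genome).  This module provides:

* binarization of raw KO count tables,
* pairwise Euclidean distances between genome KO profiles (optionally
  restricted to a KO subset such as the DNA replication and repair, DRR,
  orthologs),
* the binned minimum-distance curve: across all genome pairs, the minimum
  functional distance observed within each 1-percentage-point band of
  GC-content difference,
* per-clade KO conservation (fraction of member genomes carrying a KO),
* the genome x pathway percent matrix (KO presences merged per pathway,
  rows rescaled to sum to 100),
* a Pearson correlation screen of features against a trait with Bonferroni
  adjustment, and
* a PGLS convenience wrapper regressing a trait on per-clade KO
  conservation profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from . import phylo_comparative as pcm

# KEGG pathways / BRITE categories defining the DNA replication and repair
# (DRR) ortholog set: DNA replication, base/nucleotide excision repair,
# mismatch repair, homologous recombination, non-homologous end joining,
# and the replication / repair-and-recombination protein categories.
DRR_PATHWAYS = frozenset({"ko03030", "ko03410", "ko03420", "ko03430",
                          "ko03440", "ko03450", "ko03032", "ko03400"})

__all__ = [
    "DRR_PATHWAYS", "KOMatrix", "PathwayMap", "BinnedDistanceCurve",
    "binarize", "pairwise_euclidean", "min_distance_curve", "ko_conservation",
    "pathway_matrix", "correlate_features", "drr_pgls_r2",
]


@dataclass
class KOMatrix:
    """Genomes x KOs binary matrix."""

    genome_ids: list[str]
    ko_ids: list[str]
    M: np.ndarray

    def __post_init__(self):
        self.M = np.asarray(self.M)
        if self.M.shape != (len(self.genome_ids), len(self.ko_ids)):
            raise ValueError("matrix shape does not match id lists")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValueError("duplicate genome ids")
        if len(set(self.ko_ids)) != len(self.ko_ids):
            raise ValueError("duplicate KO ids")
        if not np.isin(self.M, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1; use binarize()")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KOMatrix":
        return cls(genome_ids=list(df.index.astype(str)),
                   ko_ids=list(df.columns.astype(str)),
                   M=df.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.genome_ids, columns=self.ko_ids)

    def subset_kos(self, kos) -> "KOMatrix":
        kos = [k for k in self.ko_ids if k in set(kos)]
        idx = [self.ko_ids.index(k) for k in kos]
        return KOMatrix(self.genome_ids, kos, self.M[:, idx])


@dataclass
class PathwayMap:
    """ko_id -> set of pathway ids (a KO may sit in several pathways)."""

    membership: dict[str, set[str]]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, ko_col: str = "ko_id",
                   pathway_col: str = "pathway_id") -> "PathwayMap":
        mem: dict[str, set[str]] = {}
        for _, row in df.iterrows():
            mem.setdefault(str(row[ko_col]), set()).add(str(row[pathway_col]))
        return cls(membership=mem)

    def pathways(self) -> list[str]:
        return sorted({p for s in self.membership.values() for p in s})

    def drr_kos(self, ko_ids) -> list[str]:
        return [k for k in ko_ids
                if self.membership.get(k, set()) & DRR_PATHWAYS]


@dataclass
class BinnedDistanceCurve:
    """Per 1-point GC-difference band: minimum functional distance, pair count.

    Bands are half-open ``[k, k+1)`` in percentage points; bands with no
    pairs carry NaN (missing), never 0.
    """

    bin_edges: np.ndarray  # length nbins+1
    min_distance: np.ndarray  # NaN where no pairs
    n_pairs: np.ndarray
    table: pd.DataFrame = field(default=None, repr=False)


def binarize(counts) -> KOMatrix:
    """Presence/absence from a non-negative count table (1 iff count >= 1)."""
    if isinstance(counts, pd.DataFrame):
        ids = list(counts.index.astype(str))
        kos = list(counts.columns.astype(str))
        arr = counts.to_numpy()
    else:
        arr = np.asarray(counts)
        ids = [f"g{i}" for i in range(arr.shape[0])]
        kos = [f"K{j:05d}" for j in range(arr.shape[1])]
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return KOMatrix(ids, kos, (arr >= 1).astype(np.int8))


def pairwise_euclidean(M: KOMatrix, feature_subset=None) -> pd.DataFrame:
    """Euclidean distance between genome rows, optionally on a KO subset.

    On binary profiles this equals the square root of the Hamming
    (symmetric-difference) count.
    """
    if feature_subset is not None:
        sub = M.subset_kos(feature_subset)
        if not sub.ko_ids:
            raise ValueError("feature subset matches no KO ids")
        M = sub
    D = squareform(pdist(M.M.astype(float), metric="euclidean"))
    return pd.DataFrame(D, index=M.genome_ids, columns=M.genome_ids)


def min_distance_curve(gc, M: KOMatrix, feature_subset=None,
                       bin_width: float = 1.0) -> BinnedDistanceCurve:
    """Minimum functional distance per GC-difference band over all pairs.

    For every unordered genome pair, the GC difference (percentage points,
    ``|gc_a - gc_b| * 100``) is assigned to a half-open band of
    ``bin_width`` points, and each band reports the smallest Euclidean
    distance among its pairs.  Vectorized over all n(n-1)/2 pairs and exact
    (no sampling), so it must agree with brute-force enumeration.
    """
    gc = np.asarray(gc, dtype=float)
    n = len(gc)
    if n != len(M.genome_ids):
        raise ValueError("gc vector must align with genome_ids")
    if n < 2:
        raise ValueError("need at least 2 genomes")
    if feature_subset is not None:
        M = M.subset_kos(feature_subset)
        if not M.ko_ids:
            raise ValueError("feature subset matches no KO ids")
    d = pdist(M.M.astype(float), metric="euclidean")
    iu = np.triu_indices(n, k=1)
    dgc = np.abs(gc[iu[0]] - gc[iu[1]]) * 100.0
    nbins = int(math.floor(dgc.max() / bin_width)) + 1
    edges = np.arange(nbins + 1) * bin_width
    # floor() implements the half-open rule: a pair exactly on an edge
    # belongs to the band whose lower edge it sits on
    which = np.minimum(np.floor(dgc / bin_width).astype(int), nbins - 1)
    counts = np.bincount(which, minlength=nbins)
    min_d = np.full(nbins, np.inf)
    np.minimum.at(min_d, which, d)
    min_d[counts == 0] = np.nan
    table = pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                          "min_dist": min_d, "n_pairs": counts})
    return BinnedDistanceCurve(bin_edges=edges, min_distance=min_d,
                               n_pairs=counts, table=table)


def ko_conservation(M: KOMatrix, clade_members: dict[str, set]) -> pd.DataFrame:
    """Clade x KO matrix of presence fractions (presence count / clade size)."""
    gidx = {g: i for i, g in enumerate(M.genome_ids)}
    rows = {}
    for clade, members in clade_members.items():
        members = list(members)
        if not members:
            raise ValueError(f"clade {clade!r} is empty")
        missing = [m for m in members if m not in gidx]
        if missing:
            raise KeyError(f"clade {clade!r} members absent from matrix: "
                           f"{missing[:5]}")
        idx = [gidx[m] for m in members]
        rows[clade] = M.M[idx].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=M.ko_ids)


def pathway_matrix(M: KOMatrix, pmap: PathwayMap) -> pd.DataFrame:
    """Genome x pathway matrix: present-KO counts per pathway, rows -> 100%.

    A KO belonging to several pathways counts once in each.  A genome with
    no pathway-mapped KO present keeps an all-zero row (flagged via the
    returned frame's ``attrs['zero_rows']``).
    """
    pathways = pmap.pathways()
    if not pathways:
        raise ValueError("pathway map is empty")
    kidx = {k: j for j, k in enumerate(M.ko_ids)}
    member_cols = {p: [] for p in pathways}
    for ko, pws in pmap.membership.items():
        if ko in kidx:
            for p in pws:
                member_cols[p].append(kidx[ko])
    raw = np.zeros((len(M.genome_ids), len(pathways)))
    for j, p in enumerate(pathways):
        if member_cols[p]:
            raw[:, j] = M.M[:, member_cols[p]].sum(axis=1)
    totals = raw.sum(axis=1)
    out = np.zeros_like(raw)
    nz = totals > 0
    out[nz] = raw[nz] / totals[nz, None] * 100.0
    df = pd.DataFrame(out, index=M.genome_ids, columns=pathways)
    df.attrs["zero_rows"] = [g for g, z in zip(M.genome_ids, ~nz) if z]
    return df


def correlate_features(features: pd.DataFrame, trait,
                       r_min: float | None = None,
                       r_max: float | None = None) -> pd.DataFrame:
    """Pearson correlation of each feature column with a trait.

    Two-sided p-values come from the t transform with n-2 degrees of
    freedom; ``p_adj = min(1, k p)`` with the Bonferroni family k equal to
    the number of testable (non-constant) features in this call, recorded
    in ``attrs['bonferroni_m']``.  Zero-variance features are reported with
    NaN statistics rather than silently dropped.  Optional display cutoffs
    keep only features with ``r > r_min`` or ``r < r_max``.
    """
    y = np.asarray(trait, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 genomes")
    if features.shape[0] != n:
        raise ValueError("feature rows must align with trait")
    if np.std(y) == 0:
        raise ValueError("trait is constant; correlations undefined")
    X = features.to_numpy(dtype=float)
    sx = X.std(axis=0)
    testable = sx > 0
    m = int(testable.sum())
    r = np.full(X.shape[1], np.nan)
    yc = y - y.mean()
    Xc = X[:, testable] - X[:, testable].mean(axis=0)
    r[testable] = (Xc.T @ yc) / (n * sx[testable] * y.std())
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p_adj = np.minimum(1.0, m * p)
    out = pd.DataFrame({"feature_id": features.columns, "r": r, "p": p,
                        "p_adj": p_adj, "n": n})
    out.attrs["bonferroni_m"] = m
    if r_min is not None or r_max is not None:
        keep = np.zeros(len(out), dtype=bool)
        if r_min is not None:
            keep |= out["r"].to_numpy() > r_min
        if r_max is not None:
            keep |= out["r"].to_numpy() < r_max
        out = out[keep].reset_index(drop=True)
    return out


def drr_pgls_r2(conservation: pd.DataFrame, trait: dict[str, float],
                tree: "pcm.PhyloTree", min_clades_present: int = 4,
                structure: str = "BM") -> "pcm.PGLSFit":
    """PGLS of a clade-level trait on DRR KO conservation profiles.

    ``conservation`` is the clade x KO fraction matrix (rows must match
    tree tips); KOs present (conservation > 0) in fewer than
    ``min_clades_present`` clades are removed before fitting, mirroring a
    "present in more than 3 families" screen.  Delegates to
    :func:`gcpanorama.phylo_comparative.pgls`.
    """
    present_in = (conservation.to_numpy() > 0).sum(axis=0)
    keep = conservation.columns[present_in >= min_clades_present]
    X = conservation[keep]
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(
            f"{k} predictors for {n} clades; prefilter KOs (e.g. raise "
            "min_clades_present or merge into pathways) so that n > k + 1")
    return pcm.pgls(trait, X, tree, structure=structure)
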