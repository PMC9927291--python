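"""Synthetic study inputs with the statistical structure the analysis assumes.

Generators for every input the pipeline consumes, so the whole analysis can
be exercised and validated without downloading genomes:

* pure-birth (Yule) time trees, ultrametric by construction;
* continuous traits (a synthetic "genomic GC") evolving by Brownian motion,
  optionally through a lambda/kappa/delta branch-length transform;
* binary genome x KO matrices in which each KO's presence probability is a
  logistic function of the genome trait (``p = logistic(alpha_j + beta_j
  z)``), with known positive, negative and null effects recorded in a truth
  table;
* bacterial-style genomes: CDS assembled from sense codons sampled from an
  exponentially GC-tilted distribution, separated by intergenic spacers,
  hitting a target genomic GC in expectation;
* nested taxonomy labels cut from the tree at per-rank height thresholds.

Determinism: every generator takes a seed; one master seed can be fanned
out to per-component child seeds with :func:`spawn_seeds`, and identical
seeds yield byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .seq_composition import CodonTableStats, GenomeRecord
from .tree import PhyloNode, PhyloTree, transform_tree_kappa, transform_vcv, vcv

__all__ = [
    "spawn_seeds", "sim_yule_tree", "sim_bm_trait", "sim_ko_matrix",
    "KOTruth", "sim_genome", "sim_taxonomy", "tilted_codon_distribution",
]


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Fan a master seed out into n independent component seeds (< 2**31)."""
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


# -- trees ------------------------------------------------------------------

def sim_yule_tree(n_tips: int, birth_rate: float = 1.0,
                  seed: int | None = None) -> PhyloTree:
    """Pure-birth tree: exponential waiting times, a uniformly chosen
    lineage splits at each event; ultrametric in time units.

    After the n-th tip appears, a final Exp(n * birth_rate) hold keeps the
    terminal branches from ending exactly at the last split.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    root = PhyloNode()
    birth_time: dict[PhyloNode, float] = {root: 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(rng.integers(k))
        for _ in range(2):
            child = PhyloNode()
            node.add_child(child)
            birth_time[child] = t
            active.append(child)
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    tree = PhyloTree.__new__(PhyloTree)
    tree.root = root
    for node in tree.preorder():
        end = t if node.is_tip else birth_time[node.children[0]]
        node.length = end - birth_time[node]
    root.length = 0.0
    for i, tip in enumerate(tree.tips()):
        tip.name = f"t{i + 1}"
    return PhyloTree(root)


# -- traits -----------------------------------------------------------------

def sim_bm_trait(tree: PhyloTree, sigma2: float = 1.0, root: float = 0.0,
                 transform: str | None = None, param: float | None = None,
                 seed: int | None = None) -> dict[str, float]:
    """Draw one trait from N(root * 1, sigma2 * transform(C)) via Cholesky.

    ``transform`` in {None, "lambda", "kappa", "delta"} applies the
    corresponding branch-length transform to the BM covariance before
    sampling, so estimator-recovery tests know the exact truth.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    labels = tree.tip_labels
    if transform == "kappa":
        C = vcv(transform_tree_kappa(tree, param))
    else:
        C = vcv(tree)
        if transform in ("lambda", "delta"):
            C = transform_vcv(C, transform, param)
        elif transform is not None:
            raise ValueError(f"unknown transform {transform!r}")
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        x = np.full(len(labels), root)
    else:
        jitter = 1e-12 * np.trace(C) / len(labels)
        L = cholesky(C + jitter * np.eye(len(labels)), lower=True)
        x = root + np.sqrt(sigma2) * (L @ rng.standard_normal(len(labels)))
    return dict(zip(labels, x))


# -- KO matrices ------------------------------------------------------------

@dataclass
class KOTruth:
    """Per-KO simulation truth: intercept alpha and trait coupling beta."""

    table: pd.DataFrame  # ko_id, alpha, beta, group in {positive,negative,null}


def sim_ko_matrix(trait: dict[str, float], n_kos: int = 300,
                  beta_magnitude: float = 2.0,
                  frac_positive: float = 1 / 3, frac_negative: float = 1 / 3,
                  alpha_sd: float = 1.0, seed: int | None = None):
    """Binary genome x KO matrix with logistic trait coupling.

    The trait is standardized to z-scores internally; KO j is present in
    genome i with probability ``logistic(alpha_j + beta_j * z_i)``.  A
    ``frac_positive`` share of KOs gets ``beta = +beta_magnitude``, a
    ``frac_negative`` share ``-beta_magnitude``, the remainder ``beta = 0``
    (null).  Returns ``(KOMatrix, KOTruth)``.
    """
    from .function_matrix import KOMatrix

    if frac_positive + frac_negative > 1 + 1e-12:
        raise ValueError("effect fractions must sum to at most 1")
    genome_ids = list(trait)
    z = np.array([trait[g] for g in genome_ids], dtype=float)
    sd = z.std()
    z = (z - z.mean()) / (sd if sd > 0 else 1.0)
    rng = np.random.default_rng(seed)
    n_pos = int(round(frac_positive * n_kos))
    n_neg = int(round(frac_negative * n_kos))
    beta = np.concatenate([np.full(n_pos, beta_magnitude),
                           np.full(n_neg, -beta_magnitude),
                           np.zeros(n_kos - n_pos - n_neg)])
    group = (["positive"] * n_pos + ["negative"] * n_neg
             + ["null"] * (n_kos - n_pos - n_neg))
    alpha = rng.normal(0.0, alpha_sd, size=n_kos)
    logit = alpha[None, :] + z[:, None] * beta[None, :]
    prob = 1.0 / (1.0 + np.exp(-logit))
    M = (rng.random((len(z), n_kos)) < prob).astype(np.int8)
    ko_ids = [f"K{j:05d}" for j in range(n_kos)]
    truth = KOTruth(pd.DataFrame({"ko_id": ko_ids, "alpha": alpha,
                                  "beta": beta, "group": group}))
    return KOMatrix(genome_ids, ko_ids, M), truth


# -- genomes ----------------------------------------------------------------

def tilted_codon_distribution(target_gc: float,
                              table: CodonTableStats | None = None,
                              tol: float = 1e-10) -> dict[str, float]:
    """Sense-codon distribution exponentially tilted to a target GC.

    Weights ``w_j proportional to exp(theta * g_j)`` with ``g_j`` the G+C
    count of codon j; theta is solved by bisection so the expected
    per-base GC of sampled codons equals ``target_gc``.  theta = 0 gives
    the uniform distribution over the 61 sense codons.
    """
    if table is None:
        table = CodonTableStats()
    codons = table.sense_codons
    g = np.array([3.0 * table.codon_gc[c] for c in codons])

    def expected_gc(theta: float) -> float:
        w = np.exp(theta * (g - g.mean()))  # centering for stability
        w /= w.sum()
        return float((w * g).sum() / 3.0)

    lo, hi = -60.0, 60.0
    lo_gc, hi_gc = expected_gc(lo), expected_gc(hi)
    target = min(max(target_gc, lo_gc + 1e-9), hi_gc - 1e-9)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if expected_gc(mid) < target:
            lo = mid
        else:
            hi = mid
    theta = 0.5 * (lo + hi)
    w = np.exp(theta * (g - g.mean()))
    w /= w.sum()
    return dict(zip(codons, w))


def sim_genome(target_gc: float, n_cds: int = 200, cds_length: int = 900,
               intergenic_length: int = 100, genome_id: str = "sim",
               uniform_codons: bool = False, seed: int | None = None,
               table: CodonTableStats | None = None) -> GenomeRecord:
    """One synthetic genome on a single contig hitting a target GC.

    Each CDS is ``cds_length`` bases of sense codons drawn from the
    GC-tilted codon distribution (or the uniform distribution if
    ``uniform_codons``), plus an appended stop codon; CDS alternate strand
    and are separated by iid intergenic spacers with per-base GC equal to
    the target.  At the default sizes the realized genomic GC lands within
    about +-1.5 percentage points of the target.
    """
    if not 0.2 <= target_gc <= 0.8:
        raise ValueError("target_gc must lie in [0.2, 0.8]")
    if cds_length % 3:
        raise ValueError("cds_length must be a multiple of 3")
    if table is None:
        table = CodonTableStats()
    rng = np.random.default_rng(seed)
    if uniform_codons:
        codons = list(table.sense_codons)
        probs = np.full(len(codons), 1.0 / len(codons))
    else:
        dist = tilted_codon_distribution(target_gc, table)
        codons = list(dist)
        probs = np.array(list(dist.values()))
    stops = sorted(table.stop_codons)
    p_base = np.array([(1 - target_gc) / 2, target_gc / 2, target_gc / 2,
                       (1 - target_gc) / 2])  # A C G T
    bases = np.array(list("ACGT"))
    parts: list[str] = []
    cds_list: list[tuple[str, int, int, str]] = []
    pos = 0
    contig = "contig1"
    for i in range(n_cds):
        spacer = "".join(rng.choice(bases, size=intergenic_length, p=p_base))
        parts.append(spacer)
        pos += intergenic_length
        idx = rng.choice(len(codons), size=cds_length // 3, p=probs)
        cds = "".join(codons[j] for j in idx) + stops[rng.integers(len(stops))]
        strand = "+" if i % 2 == 0 else "-"
        if strand == "-":
            from Bio.Seq import Seq
            cds = str(Seq(cds).reverse_complement())
        parts.append(cds)
        cds_list.append((contig, pos, pos + len(cds), strand))
        pos += len(cds)
    parts.append("".join(rng.choice(bases, size=intergenic_length, p=p_base)))
    seq = "".join(parts)
    return GenomeRecord(genome_id=genome_id, contigs={contig: seq},
                        cds_list=cds_list)


def write_genome_files(genome: GenomeRecord, fasta_path, gff_path) -> None:
    """Write a GenomeRecord as FASTA + GFF3 (1-based inclusive coordinates)."""
    with open(fasta_path, "w") as fh:
        for contig_id, seq in genome.contigs.items():
            fh.write(f">{contig_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig_id, seq in genome.contigs.items():
            fh.write(f"##sequence-region {contig_id} 1 {len(seq)}\n")
        for i, (contig_id, start, end, strand) in enumerate(genome.cds_list):
            attrs = f"ID=cds{i};gene=gene{i}"
            fh.write(f"{contig_id}\tgcpanorama_sim\tCDS\t{start + 1}\t{end}\t"
                     f".\t{strand}\t0\t{attrs}\n")


# -- taxonomy ---------------------------------------------------------------

def sim_taxonomy(tree: PhyloTree, rank_heights: dict[str, float]):
    """Nested taxonomy labels by cutting an ultrametric tree at rank heights.

    ``rank_heights`` maps rank name -> height above the tips (same units as
    branch lengths), coarse ranks higher.  A tip's label at a rank is the
    lineage (branch) crossing that height: the shallowest ancestor whose
    height is still below the threshold while its parent's is not.  Height
    0 puts every tip in its own group; a height above the root collapses
    the rank to one group.  Labels are nested across ranks by construction.
    """
    from .taxonomy_partition import TaxonomyTable

    depths = tree.depths()
    height_of = {n: None for n in tree.preorder()}
    total = tree.max_depth()
    for n in tree.preorder():
        height_of[n] = total - depths[n]
    node_id = {n: i for i, n in enumerate(tree.preorder())}
    ranks = tuple(rank_heights)
    labels: dict[str, tuple[str, ...]] = {}
    for tip in tree.tips():
        row = []
        for rank in ranks:
            h = rank_heights[rank]
            # climb while the parent is still below the threshold; the node
            # we stop at is the lineage crossing height h (the tip itself
            # for h <= 0, the root for h above the root height)
            node = tip
            while node.parent is not None and height_of[node.parent] < h:
                node = node.parent
            row.append(f"{rank}_{node_id[node]}")
        labels[tip.name] = tuple(row)
    return TaxonomyTable(ranks=ranks, labels=labels)
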