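"""Base-composition decomposition of bacterial genomes.

Computes, per genome: genomic GC, GC restricted to coding (GC_CDS) and
noncoding (GC_NCS) positions, and the two decomposition terms that separate
the contributions of amino-acid usage and synonymous codon usage:

* ``GC_AA  = sum_AA A_i * AC_i`` — the GC content implied by the genome's
  amino-acid abundances ``A_i`` if synonymous codon choice were unbiased
  (``AC_i`` is the unweighted mean GC fraction of an amino acid's codons);
* ``GC_Codon = sum_AA sum_SC AA_i * R_j * C_j`` — the GC content implied by
  the genome's synonymous codon preferences ``R_j`` (within-amino-acid
  relative codon frequencies) at a fixed, dataset-average amino-acid
  composition ``AA_i``; ``C_j`` is the GC fraction of codon ``j``.

Mean physicochemical proteome properties (``sum_AA A_i * value_i``) are
computed from a replaceable amino-acid property table.

Coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted at the parsing boundary.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
PROPERTY_NAMES = ("molecular_weight", "vdw_volume", "isoelectric_point",
                  "hydrophobicity", "polarity", "n_atoms", "nc_ratio")

__all__ = [
    "AMINO_ACIDS", "PROPERTY_NAMES",
    "GenomeRecord", "CompositionProfile", "CodonTableStats", "PropertyTable",
    "read_genome", "read_cds_fasta", "gc_fraction", "composition_basic",
    "count_codons", "gc_aa", "gc_codon", "mean_properties",
    "build_profiles", "profiles_to_frame", "write_composition_table",
]


@dataclass
class GenomeRecord:
    """Contig sequences plus CDS coordinates (0-based half-open)."""

    genome_id: str
    contigs: dict[str, str]
    cds_list: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self):
        for contig_id, start, end, strand in self.cds_list:
            if contig_id not in self.contigs:
                raise ValueError(
                    f"CDS references missing contig {contig_id!r} "
                    f"in genome {self.genome_id}")
            if not 0 <= start < end <= len(self.contigs[contig_id]):
                raise ValueError(
                    f"CDS ({contig_id}, {start}, {end}) outside contig "
                    f"bounds (length {len(self.contigs[contig_id])})")
            if strand not in "+-":
                raise ValueError(f"strand must be + or -, got {strand!r}")

    @property
    def genome_size(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class CompositionProfile:
    """All per-genome composition quantities; undefined values are NaN."""

    genome_id: str
    genome_size: int
    gc: float
    gc_cds: float
    gc_ncs: float
    aa_freq: dict[str, float]
    codon_freq: dict[str, float]
    gc_aa: float
    gc_codon: float
    property_means: dict[str, float]
    n_ambiguous: int = 0


class CodonTableStats:
    """Per-codon GC fractions and per-amino-acid synonymous-codon averages.

    ``codon_gc[j]`` is the fraction of G/C among codon j's three bases
    (one of 0, 1/3, 2/3, 1); ``aa_avg_codon_gc[i]`` is the unweighted mean
    over amino acid i's synonymous codons.
    """

    def __init__(self, trans_table: int = 11):
        self.trans_table = trans_table
        table = CodonTable.unambiguous_dna_by_id[trans_table]
        self.forward: dict[str, str] = dict(table.forward_table)
        self.stop_codons: frozenset[str] = frozenset(table.stop_codons)
        self.sense_codons: tuple[str, ...] = tuple(sorted(self.forward))
        self.codon_gc: dict[str, float] = {
            c: (c.count("G") + c.count("C")) / 3.0 for c in self.sense_codons}
        self.aa_codons: dict[str, tuple[str, ...]] = {}
        for codon, aa in self.forward.items():
            self.aa_codons.setdefault(aa, ())
        for aa in self.aa_codons:
            self.aa_codons[aa] = tuple(
                sorted(c for c, a in self.forward.items() if a == aa))
        self.aa_avg_codon_gc: dict[str, float] = {
            aa: float(np.mean([self.codon_gc[c] for c in codons]))
            for aa, codons in self.aa_codons.items()}


class PropertyTable:
    """Amino acid -> physicochemical property values.

    The bundled default uses standard published scales: Kyte-Doolittle
    hydrophobicity, Grantham polarity, average residue molecular weights,
    van der Waals side-chain volumes, free-amino-acid isoelectric points,
    and nitrogen/carbon atom counts from the molecular formulas.  Any TSV
    with an ``aa`` column plus property columns can replace it.
    """

    def __init__(self, values: Mapping[str, Mapping[str, float]]):
        missing = set(AMINO_ACIDS) - set(values)
        if missing:
            raise ValueError(f"property table missing amino acids: {sorted(missing)}")
        self.values = {aa: dict(values[aa]) for aa in AMINO_ACIDS}
        self.properties = tuple(next(iter(self.values.values())).keys())
        for aa, row in self.values.items():
            for prop, v in row.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite value for {aa}/{prop}")

    @classmethod
    def from_tsv(cls, path) -> "PropertyTable":
        df = pd.read_csv(path, sep="\t").set_index("aa")
        return cls({aa: df.loc[aa].to_dict() for aa in df.index})

    @classmethod
    def default(cls) -> "PropertyTable":
        ref = resources.files("gcpanorama").joinpath("data/aa_properties.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


# -- parsing ----------------------------------------------------------------

def read_genome(fasta_path, gff_path=None, genome_id: str | None = None
                ) -> GenomeRecord:
    """Read a genome FASTA plus optional GFF3 CDS annotation.

    GFF3 coordinates (1-based inclusive) become 0-based half-open.  A CDS
    referencing a contig absent from the FASTA is a hard error; a GFF with
    no CDS features yields an empty cds_list with a warning.
    """
    contigs = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not contigs:
        raise ValueError(f"no sequences in {fasta_path}")
    gid = genome_id or str(fasta_path).rsplit("/", 1)[-1].split(".")[0]
    cds_list: list[tuple[str, int, int, str]] = []
    if gff_path is not None:
        import gffutils

        db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True,
                                keep_order=True,
                                merge_strategy="create_unique")
        for feat in db.features_of_type("CDS"):
            if feat.seqid not in contigs:
                raise ValueError(
                    f"GFF CDS references contig {feat.seqid!r} absent from "
                    f"{fasta_path}")
            strand = feat.strand if feat.strand in "+-" else "+"
            if feat.strand not in "+-":
                logger.warning("CDS %s has strand %r; treating as +",
                               feat.id, feat.strand)
            cds_list.append((feat.seqid, feat.start - 1, feat.end, strand))
        if not cds_list:
            logger.warning("no CDS features in %s", gff_path)
    return GenomeRecord(genome_id=gid, contigs=contigs, cds_list=cds_list)


def read_cds_fasta(path, genome_id: str | None = None) -> GenomeRecord:
    """Read a CDS-only FASTA: each record is one CDS on its own 'contig'.

    GC_NCS is undefined downstream (there is no noncoding sequence), and
    genomic GC equals GC_CDS.
    """
    contigs: dict[str, str] = {}
    cds_list = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        contigs[rec.id] = seq
        cds_list.append((rec.id, 0, len(seq), "+"))
    if not contigs:
        raise ValueError(f"no sequences in {path}")
    gid = genome_id or str(path).rsplit("/", 1)[-1].split(".")[0]
    return GenomeRecord(genome_id=gid, contigs=contigs, cds_list=cds_list)


# -- composition quantities -------------------------------------------------

def gc_fraction(seq: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); N and ambiguity codes excluded.

    Returns NaN (not 0) when the sequence has no unambiguous base.
    """
    counts = Counter(seq.upper())
    gc = counts["G"] + counts["C"]
    total = gc + counts["A"] + counts["T"]
    if total == 0:
        return float("nan")
    return gc / total


def _union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    merged = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def composition_basic(g: GenomeRecord) -> tuple[int, float, float, float]:
    """(genome_size, gc, gc_cds, gc_ncs).

    GC_CDS is computed over the union of CDS intervals (each base counted
    once, strand-irrelevant for GC); GC_NCS over the complement.  With no
    CDS annotation GC_CDS is NaN and GC_NCS equals the genomic GC; with
    full coverage GC_NCS is NaN.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {c: [] for c in g.contigs}
    for contig_id, start, end, _ in g.cds_list:
        by_contig[contig_id].append((start, end))
    cds_parts: list[str] = []
    ncs_parts: list[str] = []
    for contig_id, seq in g.contigs.items():
        merged = _union_intervals(by_contig[contig_id])
        pos = 0
        for start, end in merged:
            ncs_parts.append(seq[pos:start])
            cds_parts.append(seq[start:end])
            pos = end
        ncs_parts.append(seq[pos:])
    gc = gc_fraction("".join(g.contigs.values()))
    gc_cds = gc_fraction("".join(cds_parts)) if g.cds_list else float("nan")
    ncs = "".join(ncs_parts)
    gc_ncs = gc_fraction(ncs) if ncs else float("nan")
    return g.genome_size, gc, gc_cds, gc_ncs


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def count_codons(g: GenomeRecord, table: CodonTableStats | None = None
                 ) -> tuple[Counter, Counter]:
    """Count sense codons and the amino acids they encode over all CDS.

    Minus-strand CDS are reverse-complemented; codons are read in frame 0.
    Stop codons and triplets containing ambiguity letters are excluded from
    both maps; 1-2 trailing bases of CDS whose length is not a multiple of
    three are dropped (with a logged count).
    """
    if table is None:
        table = CodonTableStats()
    if not g.cds_list:
        raise ValueError(f"genome {g.genome_id} has no CDS to count codons in")
    codon_counts: Counter = Counter()
    aa_counts: Counter = Counter()
    n_trailing = 0
    for contig_id, start, end, strand in g.cds_list:
        seq = g.contigs[contig_id][start:end]
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        rem = len(seq) % 3
        if rem:
            n_trailing += 1
            seq = seq[:len(seq) - rem]
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            aa = table.forward.get(codon)
            if aa is None:  # stop codon or ambiguity letters
                continue
            codon_counts[codon] += 1
            aa_counts[aa] += 1
    if n_trailing:
        logger.warning("genome %s: dropped trailing bases from %d CDS not "
                       "divisible by 3", g.genome_id, n_trailing)
    return codon_counts, aa_counts


def gc_aa(aa_freq: Mapping[str, float], table: CodonTableStats | None = None
          ) -> float:
    """GC content implied by amino-acid usage: sum_AA A_i * AC_i."""
    if table is None:
        table = CodonTableStats()
    return float(sum(freq * table.aa_avg_codon_gc[aa]
                     for aa, freq in aa_freq.items() if freq))


def gc_codon(codon_counts: Mapping[str, int],
             dataset_mean_aa_freq: Mapping[str, float],
             table: CodonTableStats | None = None) -> float:
    """GC content implied by synonymous codon usage at fixed amino-acid mix.

    For each amino acid, ``R_j`` is the genome's relative use of synonymous
    codon ``j``; the amino-acid weights ``AA_i`` come from the dataset-wide
    mean composition.  An amino acid never observed in the genome
    contributes ``AA_i * AC_i`` (uniform-usage fallback), keeping the sum
    over all amino acids defined.
    """
    if table is None:
        table = CodonTableStats()
    if not codon_counts:
        raise ValueError("codon_counts is empty")
    total = 0.0
    for aa, weight in dataset_mean_aa_freq.items():
        if not weight:
            continue
        codons = table.aa_codons[aa]
        aa_total = sum(codon_counts.get(c, 0) for c in codons)
        if aa_total == 0:
            total += weight * table.aa_avg_codon_gc[aa]
        else:
            total += weight * sum(
                codon_counts.get(c, 0) / aa_total * table.codon_gc[c]
                for c in codons)
    return float(total)


def mean_properties(aa_freq: Mapping[str, float], props: PropertyTable
                    ) -> dict[str, float]:
    """Abundance-weighted mean of each property: sum_AA A_i * value_i."""
    out = {}
    for prop in props.properties:
        total = 0.0
        for aa, freq in aa_freq.items():
            if aa not in props.values:
                raise KeyError(f"amino acid {aa!r} absent from property table")
            if prop not in props.values[aa]:
                raise KeyError(f"property {prop!r} absent from table")
            total += freq * props.values[aa][prop]
        out[prop] = float(total)
    return out


# -- profile assembly -------------------------------------------------------

def _normalize(counts: Counter, keys) -> dict[str, float]:
    total = sum(counts.get(k, 0) for k in keys)
    if total == 0:
        return {k: float("nan") for k in keys}
    return {k: counts.get(k, 0) / total for k in keys}


def build_profiles(genomes: list[GenomeRecord],
                   table: CodonTableStats | None = None,
                   props: PropertyTable | None = None
                   ) -> list[CompositionProfile]:
    """Two-pass profile construction over a genome set.

    Pass 1 accumulates per-genome codon/amino-acid counts; the
    dataset-mean amino-acid composition ``AA_i`` (the unweighted mean of
    per-genome frequencies) then feeds the GC_Codon term in pass 2.
    """
    if table is None:
        table = CodonTableStats()
    if props is None:
        props = PropertyTable.default()
    counted = []
    for g in genomes:
        if g.cds_list:
            counted.append(count_codons(g, table))
        else:
            counted.append((Counter(), Counter()))
    aa_freqs = [_normalize(aa_c, AMINO_ACIDS) for _, aa_c in counted]
    with_cds = [f for f, (_, aa_c) in zip(aa_freqs, counted) if sum(aa_c.values())]
    if with_cds:
        dataset_mean = {aa: float(np.mean([f[aa] for f in with_cds]))
                        for aa in AMINO_ACIDS}
    else:
        dataset_mean = None
    profiles = []
    for g, (codon_c, aa_c), aa_f in zip(genomes, counted, aa_freqs):
        size, gc, gcc, gcn = composition_basic(g)
        n_ambig = sum(s.count("N") for s in g.contigs.values())
        has_codons = sum(aa_c.values()) > 0
        codon_f = _normalize(codon_c, table.sense_codons)
        if has_codons:
            gaa = gc_aa(aa_f, table)
            gcod = gc_codon(codon_c, dataset_mean, table)
            pmeans = mean_properties(aa_f, props)
        else:
            gaa = gcod = float("nan")
            pmeans = {p: float("nan") for p in props.properties}
        profiles.append(CompositionProfile(
            genome_id=g.genome_id, genome_size=size, gc=gc, gc_cds=gcc,
            gc_ncs=gcn, aa_freq=aa_f, codon_freq=codon_f, gc_aa=gaa,
            gc_codon=gcod, property_means=pmeans, n_ambiguous=n_ambig))
    return profiles


def profiles_to_frame(profiles: list[CompositionProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"genome_id": p.genome_id, "size": p.genome_size, "gc": p.gc,
               "gc_cds": p.gc_cds, "gc_ncs": p.gc_ncs, "gc_aa": p.gc_aa,
               "gc_codon": p.gc_codon, "n_ambiguous": p.n_ambiguous}
        row.update({f"aa_{aa}": p.aa_freq[aa] for aa in AMINO_ACIDS})
        row.update({f"codon_{c}": p.codon_freq[c] for c in sorted(p.codon_freq)})
        row.update({f"prop_{k}": v for k, v in p.property_means.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_composition_table(profiles: list[CompositionProfile], path) -> None:
    df = profiles_to_frame(profiles)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
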