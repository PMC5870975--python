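"""Nucleotide composition: A+T content, AT-skew and GC-skew per partition.

Skews are the usual strand-asymmetry statistics

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed over the counted bases of a partition.  The whole-genome values
are taken on the majority (J) strand as stored; per-gene values are taken
on the sense strand of each gene.  ``N`` never enters a numerator or a
denominator.  Values are kept at full precision internally and rounded
only in the tabular report (percentages to 0.1, skews to 0.001).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from . import references
from .mito_io import extract_gene, framed_cds, sense_codons
from .model import MitoGenome


@dataclass
class SkewReport:
    partition: str
    length_bp: int          # counted bases (N excluded)
    at_content: float       # fraction in [0, 1]
    at_skew: float          # NaN when A+T == 0
    gc_skew: float          # NaN when G+C == 0


def base_counts(seq: str) -> dict[str, int]:
    """Counts of A, C, G, T; N is excluded, anything else is an error."""
    c = Counter(seq.upper())
    bad = set(c) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid symbols: {sorted(bad)}")
    return {b: c.get(b, 0) for b in "ACGT"}


def skews(seq: str) -> tuple[float, float, float]:
    """(A+T content, AT-skew, GC-skew) of a sequence; NaN-flagged when a
    denominator is zero."""
    if not seq:
        raise ValueError("empty sequence")
    c = base_counts(seq)
    at = c["A"] + c["T"]
    gc = c["G"] + c["C"]
    total = at + gc
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    at_content = at / total
    at_skew = (c["A"] - c["T"]) / at if at else math.nan
    gc_skew = (c["G"] - c["C"]) / gc if gc else math.nan
    return at_content, at_skew, gc_skew


def _report(partition: str, seq: str) -> SkewReport:
    c = base_counts(seq)
    n_counted = sum(c.values())
    at_content, at_skew, gc_skew = skews(seq)
    return SkewReport(partition, n_counted, at_content, at_skew, gc_skew)


def codon_position_sequences(genome: MitoGenome) -> tuple[str, str, str]:
    """Pooled 1st/2nd/3rd codon-position bases of the 13 PCGs.

    Each gene is framed from its codon_start; the trailing partial codon
    (incomplete terminator) is dropped, complete stop codons are kept.
    """
    pos = ["", "", ""]
    for name in references.PCG_NAMES:
        if not genome.has_feature(name):
            continue
        seq = framed_cds(genome, genome.feature(name))
        seq = seq[: 3 * (len(seq) // 3)]
        for k in range(3):
            pos[k] += seq[k::3]
    return pos[0], pos[1], pos[2]


def partition_composition(genome: MitoGenome) -> list[SkewReport]:
    """Skew reports for: whole genome (J strand), pooled PCGs (sense),
    PCG codon positions 1-3, pooled tRNAs (sense), rrnL, rrnS, CR.

    Missing partitions are omitted with a warning.  The pooled-PCG report
    includes terminators (they are genomic sequence); the codon-position
    reports drop trailing partial codons.
    """
    reports = [_report("whole_genome", genome.sequence)]
    pcg_concat = "".join(
        extract_gene(genome, genome.feature(n))
        for n in references.PCG_NAMES if genome.has_feature(n))
    missing_pcg = [n for n in references.PCG_NAMES if not genome.has_feature(n)]
    if missing_pcg:
        warnings.warn(f"{genome.identifier}: missing PCGs {missing_pcg}; "
                      "pooled-PCG partitions incomplete", stacklevel=2)
    if pcg_concat:
        reports.append(_report("PCG", pcg_concat))
        for k, seq in enumerate(codon_position_sequences(genome), start=1):
            if seq:
                reports.append(_report(f"PCG_pos{k}", seq))
    trna_concat = "".join(
        extract_gene(genome, f) for f in genome.features_of_kind("tRNA"))
    if trna_concat:
        reports.append(_report("tRNA", trna_concat))
    else:
        warnings.warn(f"{genome.identifier}: no tRNA features", stacklevel=2)
    for name in ("rrnL", "rrnS"):
        if genome.has_feature(name):
            reports.append(_report(name, extract_gene(genome, genome.feature(name))))
        else:
            warnings.warn(f"{genome.identifier}: missing {name}", stacklevel=2)
    cr = genome.features_of_kind("CR")
    if cr:
        reports.append(_report("CR", extract_gene(genome, cr[0])))
    else:
        warnings.warn(f"{genome.identifier}: no annotated control region",
                      stacklevel=2)
    return reports


def composition_report(genomes: list[MitoGenome]) -> pd.DataFrame:
    """Tidy per-genome, per-partition table with report-time rounding."""
    rows = []
    for g in genomes:
        for r in partition_composition(g):
            rows.append({
                "genome": g.identifier,
                "partition": r.partition,
                "length_bp": r.length_bp,
                "AT_pct": round(100 * r.at_content, 1),
                "AT_skew": round(r.at_skew, 3),
                "GC_skew": round(r.gc_skew, 3),
            })
    return pd.DataFrame(rows, columns=["genome", "partition", "length_bp",
                                       "AT_pct", "AT_skew", "GC_skew"])


def length_stats(genomes: list[MitoGenome]) -> pd.DataFrame:
    """Per-gene min/max/mean length across genomes, plus whole-genome and
    control-region rows."""
    if not genomes:
        raise ValueError("no genomes given")
    lengths: dict[str, list[int]] = {}
    for g in genomes:
        lengths.setdefault("whole_genome", []).append(len(g.sequence))
        for f in g.features:
            if f.kind in ("PCG", "tRNA", "rRNA", "CR"):
                lengths.setdefault(f.name, []).append(f.length(len(g.sequence)))
    rows = []
    order = ["whole_genome"] + sorted(k for k in lengths if k != "whole_genome")
    for name in order:
        vals = lengths[name]
        rows.append({
            "gene": name, "n": len(vals), "min_bp": min(vals),
            "max_bp": max(vals), "mean_bp": sum(vals) / len(vals),
        })
    return pd.DataFrame(rows, columns=["gene", "n", "min_bp", "max_bp", "mean_bp"])


# the codon census framing (sense_codons) is re-exported for callers that
# want composition and census to share one framing rule
__all__ = [
    "SkewReport", "base_counts", "skews", "partition_composition",
    "composition_report", "length_stats", "codon_position_sequences",
    "sense_codons",
]
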