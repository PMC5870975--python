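"""Codon census of the 13 protein-coding genes under the invertebrate
mitochondrial code: start/stop survey, RSCU, top codons, missing codons.

Census conventions (both switchable):

* start codons are counted — COI's CGA start is a translated codon, and
  excluding it would make CGA spuriously missing in some taxa;
* terminators (complete UAA/UAG or incomplete T/TA) are excluded — a
  missing-codon census is about sense codons.

RSCU(c) = count(c) * |F| / sum over the synonymous family F of c; a family
with zero total is reported as RSCU 0 and flagged undefined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .genetic_code import (FAMILIES, SENSE_CODONS, STOP_CODONS, amino_acid,
                           degeneracy_order, dna_to_rna, family_of)
from .mito_io import framed_cds, sense_codons
from .model import MitoGenome
from .references import PCG_NAMES

ALL_CODONS = tuple(sorted(SENSE_CODONS) + sorted(STOP_CODONS))


@dataclass
class CodonCensus:
    genome_id: str
    counts: dict[str, int]                    # RNA codon -> count, 64 keys
    includes_start: bool = True
    includes_terminator: bool = False

    @property
    def sense_codon_count(self) -> int:
        return sum(self.counts[c] for c in SENSE_CODONS)


@dataclass
class StartStopSurvey:
    """Per-gene start codon (DNA alphabet) and terminator.

    Terminators are UAA/UAG (complete, RNA alphabet) or T/TA (incomplete,
    the trailing bases completed to UAA by polyadenylation).  Anything
    else is kept verbatim and flagged non-canonical.
    """

    genome_id: str
    starts: dict[str, str] = field(default_factory=dict)
    stops: dict[str, str] = field(default_factory=dict)
    non_canonical: set[str] = field(default_factory=set)


def _terminator(framed: str) -> tuple[str, list[str]]:
    """Split a framed CDS into (terminator label, sense DNA codons)."""
    ncod = len(framed) // 3
    codons = [framed[3 * i: 3 * i + 3] for i in range(ncod)]
    trailing = framed[3 * ncod:]
    if trailing:
        return trailing, codons
    if codons and dna_to_rna(codons[-1]) in STOP_CODONS:
        return dna_to_rna(codons[-1]), codons[:-1]
    return "", codons


def codon_census(genome: MitoGenome, include_start: bool = True,
                 include_terminator: bool = False) -> CodonCensus:
    """Count sense codons over all annotated PCGs.

    Each PCG is read on its sense strand, framed from codon_start, and
    stepped in non-overlapping 3-mers from the first codon through the
    last complete codon preceding the terminator.  Internal stop codons
    trigger a warning (the annotation is suspect) but are still excluded
    from the sense count.
    """
    counts = {c: 0 for c in ALL_CODONS}
    for name in PCG_NAMES:
        if not genome.has_feature(name):
            continue
        feature = genome.feature(name)
        framed = framed_cds(genome, feature)
        if len(framed) < 6:
            raise ValueError(f"{genome.identifier}/{name}: framed CDS shorter "
                             "than two codons")
        terminator, codons = _terminator(framed)
        if not include_start:
            codons = codons[1:]
        for pos, codon in enumerate(codons):
            rna = dna_to_rna(codon)
            if rna in STOP_CODONS:
                warnings.warn(
                    f"{genome.identifier}/{name}: internal stop codon {rna} "
                    f"at codon {pos + 1}", stacklevel=2)
                continue
            counts[rna] += 1
        if include_terminator and terminator in ("UAA", "UAG"):
            counts[terminator] += 1
    return CodonCensus(genome.identifier, counts, include_start,
                       include_terminator)


def start_stop_survey(genome: MitoGenome) -> StartStopSurvey:
    """Start codon (DNA) and terminator class for every annotated PCG."""
    survey = StartStopSurvey(genome.identifier)
    for name in PCG_NAMES:
        if not genome.has_feature(name):
            continue
        framed = framed_cds(genome, genome.feature(name))
        terminator, codons = _terminator(framed)
        survey.starts[name] = codons[0] if codons else ""
        if terminator in ("UAA", "UAG", "T", "TA"):
            survey.stops[name] = terminator
        else:
            survey.stops[name] = terminator
            survey.non_canonical.add(name)
    return survey


def rscu(census: CodonCensus) -> dict[str, float]:
    """Relative synonymous codon usage for all 62 sense codons.

    Families with zero total usage get RSCU 0.0 for every member (flagged
    through :func:`undefined_families`).
    """
    out: dict[str, float] = {}
    for family in FAMILIES.values():
        total = sum(census.counts[c] for c in family)
        for c in family:
            out[c] = (census.counts[c] * len(family) / total) if total else 0.0
    return out


def undefined_families(census: CodonCensus) -> set[str]:
    """Amino acids whose whole synonymous family is unused (RSCU undefined)."""
    return {aa for aa, family in FAMILIES.items()
            if sum(census.counts[c] for c in family) == 0}


def missing_codons(census: CodonCensus) -> list[str]:
    """Sense codons absent from the census, ordered by descending family
    size then alphabetically (RNA alphabet)."""
    absent = [c for c in SENSE_CODONS if census.counts[c] == 0]
    return degeneracy_order(absent)


def format_missing(codons: list[str]) -> list[str]:
    """Render missing codons the way comparative tables print them,
    e.g. ``AGG(S)``."""
    return [f"{c}({amino_acid(c)})" for c in codons]


def top_codons(census: CodonCensus, k: int) -> list[str]:
    """The k most used sense codons, count-descending, ties alphabetical."""
    if k < 1:
        raise ValueError("k must be >= 1")
    present = [c for c in SENSE_CODONS if census.counts[c] > 0]
    ranked = sorted(present, key=lambda c: (-census.counts[c], c))
    return ranked[:k]


# ---------------------------------------------------------------------------
# tabular reports


def census_table(censuses: list[CodonCensus]) -> pd.DataFrame:
    rows = [{"genome": c.genome_id, **{k: c.counts[k] for k in ALL_CODONS}}
            for c in censuses]
    return pd.DataFrame(rows, columns=["genome", *ALL_CODONS])


def rscu_table(censuses: list[CodonCensus]) -> pd.DataFrame:
    rows = []
    for c in censuses:
        vals = rscu(c)
        rows.append({"genome": c.genome_id,
                     **{k: round(vals[k], 3) for k in SENSE_CODONS}})
    return pd.DataFrame(rows, columns=["genome", *SENSE_CODONS])


def missing_codon_table(censuses: list[CodonCensus]) -> pd.DataFrame:
    rows = [{"genome": c.genome_id,
             "n_missing": len(missing_codons(c)),
             "missing_codons": " ".join(format_missing(missing_codons(c)))}
            for c in censuses]
    return pd.DataFrame(rows, columns=["genome", "n_missing", "missing_codons"])


def start_stop_table(surveys: list[StartStopSurvey]) -> pd.DataFrame:
    rows = []
    for s in surveys:
        for gene in sorted(s.starts):
            rows.append({"genome": s.genome_id, "gene": gene,
                         "start_codon": s.starts[gene],
                         "stop_codon": s.stops[gene],
                         "incomplete": s.stops[gene] in ("T", "TA"),
                         "non_canonical": gene in s.non_canonical})
    return pd.DataFrame(rows, columns=["genome", "gene", "start_codon",
                                       "stop_codon", "incomplete",
                                       "non_canonical"])


__all__ = [
    "CodonCensus", "StartStopSurvey", "codon_census", "start_stop_survey",
    "rscu", "undefined_families", "missing_codons", "format_missing",
    "top_codons", "census_table", "rscu_table", "missing_codon_table",
    "start_stop_table", "sense_codons",
]
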