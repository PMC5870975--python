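"""Non-coding regions: control-region location, degenerate-motif scanning,
conserved-block discovery across aligned control regions, and the
spacer-versus-gene similarity test.

The lepidopteran control region (A+T-rich region) carries a small set of
conserved elements: the ATAGA block (CBS-1) followed by a poly-T stretch,
an (AT)n microsatellite with an A(T)TTTA block (CBS-2) upstream of it, an
ACCRT block (CBS-3) near the 3' end, and — in the trnS-ND1 spacer — the
ATACTAW binding motif of the transcription termination factor (DmTTF).
Motif patterns use IUPAC one-letter codes; run/repeat elements are
reported as maximal hits only.  All hit coordinates are 1-based inclusive
within the scanned region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .alignment_msa import LocalAlignment, local_align
from .model import GeneFeature, MitoGenome, reverse_complement
from .trna_profile import column_identities

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_TO_IUPAC = {frozenset(v): k for k, v in IUPAC.items() if k != "U"}


@dataclass
class MotifDef:
    """A scannable element: an IUPAC pattern, a homopolymer run
    (``RUN:T:5`` = T-run of length >= 5) or a dinucleotide repeat
    (``REPEAT:AT:3`` = (AT)n with n >= 3)."""

    motif_id: str
    pattern: str

    @property
    def kind(self) -> str:
        if self.pattern.startswith("RUN:"):
            return "run"
        if self.pattern.startswith("REPEAT:"):
            return "repeat"
        return "iupac"


#: default motif set; CBS2 "A(T)TTTA" is read as {ATTTA, ATTTTA} via ATTTTA
#: with one optional T, expressed as two explicit alternatives.
DEFAULT_MOTIFS = (
    MotifDef("CBS1", "ATAGA"),
    MotifDef("CBS2", "ATTTA|ATTTTA"),
    MotifDef("CBS3", "ACCRT"),
    MotifDef("POLY_T", "RUN:T:5"),
    MotifDef("POLY_A", "RUN:A:5"),
    MotifDef("AT_MICROSAT", "REPEAT:AT:3"),
    MotifDef("DmTTF_ATACTAW", "ATACTAW"),
)


@dataclass
class MotifHit:
    motif_id: str
    start: int      # 1-based inclusive within the scanned region (J strand)
    end: int
    matched: str    # the J-strand slice region[start-1:end]
    strand: str = "J"


def iupac_match(pattern: str, text: str) -> bool:
    """Exact IUPAC match of *pattern* against *text* (equal lengths)."""
    if len(pattern) != len(text):
        return False
    for p, t in zip(pattern.upper(), text.upper()):
        if p not in IUPAC:
            raise ValueError(f"unknown IUPAC letter {p!r}")
        if t.replace("U", "T") not in IUPAC[p]:
            return False
    return True


def _scan_iupac(region: str, pattern: str):
    for alt in pattern.split("|"):
        for p in alt:
            if p.upper() not in IUPAC:
                raise ValueError(f"unknown IUPAC letter {p!r} in pattern {pattern!r}")
        k = len(alt)
        for i in range(len(region) - k + 1):
            if iupac_match(alt, region[i: i + k]):
                yield i, i + k - 1


def _scan_run(region: str, base: str, n_min: int):
    for m in re.finditer(f"{base}{{{n_min},}}", region):
        yield m.start(), m.end() - 1


def _scan_repeat(region: str, unit: str, n_min: int):
    for m in re.finditer(f"(?:{unit}){{{n_min},}}", region):
        yield m.start(), m.end() - 1


def _hits_one_strand(region: str, motifs) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for motif in motifs:
        if motif.kind == "run":
            _, base, n = motif.pattern.split(":")
            spans = _scan_run(region, base.upper(), int(n))
        elif motif.kind == "repeat":
            _, unit, n = motif.pattern.split(":")
            spans = _scan_repeat(region, unit.upper(), int(n))
        else:
            spans = _scan_iupac(region, motif.pattern.upper())
        for i, j in spans:
            hits.append(MotifHit(motif.motif_id, i + 1, j + 1,
                                 region[i: j + 1]))
    return hits


def scan_motifs(region: str, motifs=DEFAULT_MOTIFS,
                strands: tuple[str, ...] = ("J",)) -> list[MotifHit]:
    """Scan a region for every motif in the set.

    Overlapping hits of distinct motifs are all reported; run/repeat
    motifs report maximal hits only.  With ``strands=("J", "N")`` the
    reverse complement is scanned too and hit coordinates are mapped back
    onto the forward (J) strand; ``matched`` is always the J-strand slice.
    """
    if not region:
        raise ValueError("empty region")
    region = region.upper()
    hits = []
    if "J" in strands:
        hits.extend(_hits_one_strand(region, motifs))
    if "N" in strands:
        n = len(region)
        for h in _hits_one_strand(reverse_complement(region), motifs):
            start = n - h.end + 1
            end = n - h.start + 1
            hits.append(MotifHit(h.motif_id, start, end,
                                 region[start - 1: end], strand="N"))
    hits.sort(key=lambda h: (h.start, h.end, h.motif_id, h.strand))
    return hits


# ---------------------------------------------------------------------------
# control region & spacers


def locate_control_region(genome: MitoGenome, min_gap: int = 50) -> GeneFeature:
    """The annotated control region, or — when absent — the largest
    non-coding gap between rrnS and trnM (the Ditrysia convention),
    returned as an inferred CR feature."""
    annotated = genome.features_of_kind("CR")
    if annotated:
        return annotated[0]
    gaps = [g for g in intergenic_spacers(genome, min_length=min_gap)
            if g.name == "rrnS-trnM"]
    if not gaps:
        raise ValueError(f"{genome.identifier}: no CR candidate (no gap "
                         f">= {min_gap} bp between rrnS and trnM)")
    best = max(gaps, key=lambda f: f.length(len(genome.sequence)))
    return best.copy(name="CR", kind="CR", inferred=True)


def intergenic_spacers(genome: MitoGenome, min_length: int = 1) -> list[GeneFeature]:
    """Gaps between consecutive annotated genes on the circular molecule.

    Each gap is named ``upstream-downstream`` after its J-strand flanking
    genes and returned as a spacer feature (CR annotations count as genes;
    spacer annotations are ignored).
    """
    n = len(genome.sequence)
    genes = sorted(
        (f for f in genome.features if f.kind in ("PCG", "tRNA", "rRNA", "CR")),
        key=lambda f: f.start)
    if not genes:
        return []
    out: list[GeneFeature] = []
    for a, b in zip(genes, genes[1:] + genes[:1]):
        # for an origin-wrapping feature, a.end is already in [1, n]
        gap_start = a.end + 1
        if b is genes[0] and not a.wraps_origin:
            gap_end = b.start - 1 + n  # wrap-around gap back to the first gene
        else:
            gap_end = b.start - 1
        length = gap_end - gap_start + 1
        if length < min_length or length <= 0:
            continue
        if gap_end > n:  # wraps the origin
            out.append(GeneFeature(name=f"{a.name}-{b.name}", kind="spacer",
                                   start=gap_start, end=gap_end - n,
                                   wraps_origin=True))
        else:
            out.append(GeneFeature(name=f"{a.name}-{b.name}", kind="spacer",
                                   start=gap_start, end=gap_end))
    return out


# ---------------------------------------------------------------------------
# conserved blocks


@dataclass
class ConservedBlock:
    columns: tuple[int, int]   # 1-based inclusive alignment columns
    mean_identity: float
    consensus: str             # minimal IUPAC codes; '-' for gap-majority
    support: float             # fraction of taxa non-gap over the block


def _column_consensus(rows: list[str], k: int) -> str:
    residues = frozenset(r[k].replace("U", "T") for r in rows if r[k] != "-")
    if not residues:
        return "-"
    return _TO_IUPAC[residues]


def find_conserved_blocks(rows: list[str], window: int = 5,
                          min_identity: float = 0.9,
                          min_support: float = 0.9) -> list[ConservedBlock]:
    """Sliding-window conserved-block caller over an alignment.

    Windows whose mean column identity is >= ``min_identity`` and whose
    mean non-gap support is >= ``min_support`` qualify; overlapping
    qualifying windows are merged into maximal blocks.  Invariant under
    taxon reordering.
    """
    if len(rows) < 3:
        raise ValueError("find_conserved_blocks requires >= 3 aligned taxa")
    ncol = len(rows[0])
    if window > ncol:
        raise ValueError(f"window {window} exceeds alignment length {ncol}")
    if any(len(r) != ncol for r in rows):
        raise ValueError("alignment rows differ in length")
    ident = column_identities(rows)
    support = [sum(r[k] != "-" for r in rows) / len(rows) for k in range(ncol)]
    qualifying: list[tuple[int, int]] = []
    for s in range(ncol - window + 1):
        w = slice(s, s + window)
        if (sum(ident[w]) / window >= min_identity
                and sum(support[w]) / window >= min_support):
            qualifying.append((s, s + window - 1))
    if not qualifying:
        return []
    merged: list[list[int]] = [list(qualifying[0])]
    for s, e in qualifying[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    blocks = []
    for s, e in merged:
        cols = range(s, e + 1)
        blocks.append(ConservedBlock(
            columns=(s + 1, e + 1),
            mean_identity=sum(ident[k] for k in cols) / len(cols),
            consensus="".join(_column_consensus(rows, k) for k in cols),
            support=sum(support[k] for k in cols) / len(cols),
        ))
    return blocks


# ---------------------------------------------------------------------------
# spacer vs gene similarity


def spacer_similarity(spacer: str, gene: str, match: int = 1,
                      mismatch: int = -1, gap_open: int = -2,
                      gap_extend: int = -1) -> LocalAlignment:
    """Best local alignment of an intergenic spacer against a gene.

    Used for the trnQ-ND2 spacer, whose similarity to ND2 suggests it is
    the decayed remnant of a duplicated ND2 copy.  Returns the
    Smith-Waterman result: identity is matches over aligned columns, and
    ``subject_span`` locates the matching fragment within the gene
    (1-based inclusive).
    """
    if not spacer or not gene:
        raise ValueError("spacer_similarity requires non-empty sequences")
    return local_align(spacer.upper(), gene.upper(), match=match,
                       mismatch=mismatch, gap_open=gap_open,
                       gap_extend=gap_extend)
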