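"""tRNA cloverleaf profiling: structural region mapping, stem mismatch
detection, and cross-genome conservation (percentage of identical
nucleotides).

A cloverleaf is described by a dot-bracket string over the sense-strand
sequence.  The four paired blocks in 5'->3' order are the acceptor, DHU,
anticodon and TψC stems; trnS^AGN, whose DHU stem is replaced by an
unpaired loop in most insects, parses as a three-stem structure with an
empty DHU stem.

"Percentage of identical nucleotides" is implemented as the frequency of
the modal residue per aligned column, gaps excluded from numerator and
denominator (the field reports the statistic without a formula; a mean
pairwise identity alternative is available via ``method='pairwise'``).
Positions in region maps are 0-based.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple

import pandas as pd

from .alignment_msa import DEFAULT_SCORES, Alignment, center_star_msa

REGION_LABELS = ("acceptor_stem", "DHU_stem", "DHU_loop", "anticodon_stem",
                 "anticodon_loop", "variable_loop", "TpsiC_stem", "TpsiC_loop")

VALID_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
               ("G", "U"), ("U", "G")}


class Mismatch(NamedTuple):
    pos5: int
    pos3: int
    pair: str
    stem: str


@dataclass
class TrnaStructure:
    sequence: str
    dotbracket: str
    regions: dict[str, list[int]]
    stem_pairs: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def anticodon(self) -> str:
        loop = self.regions["anticodon_loop"]
        mid = len(loop) // 2
        return "".join(self.sequence[p] for p in loop[mid - 1: mid + 2])


def _pair_map(dotbracket: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def _helices(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group base pairs into stems (stacked runs of nested pairs)."""
    helices: list[list[tuple[int, int]]] = []
    for i, j in pairs:
        if helices and helices[-1][-1] == (i - 1, j + 1):
            helices[-1].append((i, j))
        else:
            helices.append([(i, j)])
    return helices


def parse_structure(seq: str, dotbracket: str) -> TrnaStructure:
    """Map a dot-bracket cloverleaf onto named structural regions.

    Raises ``ValueError("non-cloverleaf ...")`` unless the structure has
    exactly four stems, or three stems with the DHU arm absent
    (trnS^AGN-style).
    """
    seq = seq.upper().replace("T", "U")
    if len(seq) != len(dotbracket):
        raise ValueError("sequence and structure lengths differ")
    pairs = _pair_map(dotbracket)
    helices = _helices(pairs)
    if len(helices) not in (3, 4):
        raise ValueError(f"non-cloverleaf: {len(helices)} stems (expected 4, "
                         "or 3 for a DHU-less trnS^AGN)")
    # the acceptor stem pairs the 5' and 3' extremities and must enclose
    # the three (or two) hairpin arms
    acceptor = helices[0]
    arms = helices[1:]
    if any(i < acceptor[-1][0] or j > acceptor[-1][1] for arm in arms
           for i, j in arm):
        raise ValueError("non-cloverleaf: arms not nested inside acceptor stem")
    if len(arms) == 3:
        dhu, anticodon_arm, tpsic = arms
    else:
        dhu = []
        anticodon_arm, tpsic = arms

    regions: dict[str, list[int]] = {label: [] for label in REGION_LABELS}
    stem_pairs: dict[str, list[tuple[int, int]]] = {
        "acceptor_stem": acceptor, "DHU_stem": dhu,
        "anticodon_stem": anticodon_arm, "TpsiC_stem": tpsic,
    }
    for label, arm in stem_pairs.items():
        for i, j in arm:
            regions[label].extend((i, j))
        regions[label].sort()

    def hairpin_loop(arm: list[tuple[int, int]]) -> list[int]:
        inner_i, inner_j = arm[-1]
        return list(range(inner_i + 1, inner_j))

    if dhu:
        regions["DHU_loop"] = hairpin_loop(dhu)
    else:
        # DHU arm replaced by an unpaired run between the acceptor 5' side
        # and the anticodon stem
        lo = acceptor[-1][0] + 1
        hi = anticodon_arm[0][0]
        regions["DHU_loop"] = list(range(lo, hi))
    regions["anticodon_loop"] = hairpin_loop(anticodon_arm)
    regions["TpsiC_loop"] = hairpin_loop(tpsic)
    regions["variable_loop"] = list(range(anticodon_arm[0][1] + 1, tpsic[0][0]))
    return TrnaStructure(seq, dotbracket, regions, stem_pairs)


def detect_mismatches(structure: TrnaStructure) -> list[Mismatch]:
    """Stem pairs outside {AU, UA, GC, CG, GU, UG} (G·U wobble is valid)."""
    out: list[Mismatch] = []
    for stem, pairs in structure.stem_pairs.items():
        for i, j in pairs:
            pair = (structure.sequence[i], structure.sequence[j])
            if pair not in VALID_PAIRS:
                out.append(Mismatch(i, j, "".join(pair), stem))
    out.sort(key=lambda m: m.pos5)
    return out


# ---------------------------------------------------------------------------
# conservation


@dataclass
class ConservationProfile:
    gene: str
    n_taxa: int
    per_site_identity: list[float]
    per_region_identity: dict[str, float]
    strand: str = "J"

    @property
    def mean_identity(self) -> float:
        return sum(self.per_site_identity) / len(self.per_site_identity)


def column_identities(rows: list[str], method: str = "modal") -> list[float]:
    """Per-column identity of an alignment.

    ``modal``: frequency of the most common non-gap residue among non-gap
    residues.  ``pairwise``: mean pairwise identity over pairs with both
    residues non-gap.  Columns with no informative residues score 0.
    """
    ncol = len(rows[0])
    out = []
    for k in range(ncol):
        col = [r[k] for r in rows if r[k] != "-"]
        if not col:
            out.append(0.0)
            continue
        if method == "modal":
            out.append(Counter(col).most_common(1)[0][1] / len(col))
        elif method == "pairwise":
            pairs = list(combinations(col, 2))
            if not pairs:
                out.append(1.0)
            else:
                out.append(sum(a == b for a, b in pairs) / len(pairs))
        else:
            raise ValueError(f"unknown identity method {method!r}")
    return out


def conservation_profile(orthologs: list[tuple[str, str]], gene: str = "",
                         strand: str = "J",
                         reference_structure: TrnaStructure | None = None,
                         reference_taxon: str | None = None,
                         scores=DEFAULT_SCORES, prealigned: bool = False,
                         method: str = "modal") -> ConservationProfile:
    """Cross-genome per-site (and per-region) conservation of one tRNA.

    Region means are taken over the columns onto which the reference
    taxon's structure positions project through the alignment; the
    reference defaults to the first taxon in input order.
    """
    if len(orthologs) < 2:
        raise ValueError("conservation_profile requires >= 2 sequences")
    ids = [i for i, _ in orthologs]
    seqs = [s.upper().replace("T", "U") for _, s in orthologs]
    if prealigned:
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("prealigned sequences differ in length")
        aln = Alignment(ids, seqs)
    else:
        aln = center_star_msa(seqs, scores, ids=ids)
    per_site = column_identities(aln.rows, method=method)
    per_region: dict[str, float] = {}
    if reference_structure is not None:
        ref_idx = ids.index(reference_taxon) if reference_taxon else 0
        ref_row = aln.rows[ref_idx]
        # map ungapped reference positions to alignment columns
        pos2col = [k for k, ch in enumerate(ref_row) if ch != "-"]
        if len(pos2col) != len(reference_structure.sequence):
            raise ValueError("reference structure length does not match the "
                             "reference sequence in the alignment")
        for label, positions in reference_structure.regions.items():
            if positions:
                per_region[label] = sum(per_site[pos2col[p]]
                                        for p in positions) / len(positions)
    return ConservationProfile(gene, len(ids), per_site, per_region, strand)


@dataclass
class StrandComparison:
    by_strand: pd.DataFrame
    difference: float               # mean J identity minus mean N identity
    region_ranking: pd.DataFrame


def strand_conservation_compare(profiles: list[ConservationProfile]) -> StrandComparison:
    """Mean conservation per strand group, their difference, and per-region
    ranking pooled over all profiles that carry region means."""
    groups: dict[str, list[float]] = {"J": [], "N": []}
    for p in profiles:
        groups.setdefault(p.strand, []).append(p.mean_identity)
    rows = [{"strand": s, "n_trnas": len(v),
             "mean_identity": sum(v) / len(v) if v else float("nan")}
            for s, v in groups.items()]
    by_strand = pd.DataFrame(rows, columns=["strand", "n_trnas", "mean_identity"])
    mj = by_strand.loc[by_strand.strand == "J", "mean_identity"].iloc[0]
    mn = by_strand.loc[by_strand.strand == "N", "mean_identity"].iloc[0]
    region_vals: dict[str, list[float]] = {}
    for p in profiles:
        for label, val in p.per_region_identity.items():
            region_vals.setdefault(label, []).append(val)
    ranking = pd.DataFrame(
        [{"region": label, "mean_identity": sum(v) / len(v)}
         for label, v in region_vals.items()],
        columns=["region", "mean_identity"],
    ).sort_values("mean_identity", ascending=False, ignore_index=True)
    return StrandComparison(by_strand, mj - mn, ranking)
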