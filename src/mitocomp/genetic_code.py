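"""Invertebrate mitochondrial genetic code (NCBI translation table 5).

Relative to the standard code: AGA/AGG encode Ser (giving an eight-member
serine family), UGA encodes Trp, and AUA encodes Met.  The only stop codons
are UAA and UAG, leaving 62 sense codons.
"""

from __future__ import annotations

from functools import lru_cache

_BASES = "UCAG"

# laid out in the classic U/C/A/G table order
_AA = (
    "FFLL" "SSSS" "YY**" "CCWW"   # UUN UCN UAN UGN
    "LLLL" "PPPP" "HHQQ" "RRRR"   # CUN CCN CAN CGN
    "IIMM" "TTTT" "NNKK" "SSSS"   # AUN ACN AAN AGN  (AGA/AGG = Ser)
    "VVVV" "AAAA" "DDEE" "GGGG"   # GUN GCN GAN GGN
)

CODON_TABLE: dict[str, str] = {}
for i, b1 in enumerate(_BASES):
    for j, b2 in enumerate(_BASES):
        for k, b3 in enumerate(_BASES):
            CODON_TABLE[b1 + b2 + b3] = _AA[16 * i + 4 * j + k]

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in CODON_TABLE if c not in STOP_CODONS))
assert len(SENSE_CODONS) == 62

#: amino acid -> tuple of synonymous codons (sense codons only)
FAMILIES: dict[str, tuple[str, ...]] = {}
for codon in SENSE_CODONS:
    FAMILIES.setdefault(CODON_TABLE[codon], ())
FAMILIES = {
    aa: tuple(sorted(c for c in SENSE_CODONS if CODON_TABLE[c] == aa))
    for aa in FAMILIES
}


def amino_acid(codon: str) -> str:
    """One-letter amino acid for an RNA codon ('*' for UAA/UAG)."""
    return CODON_TABLE[codon.upper().replace("T", "U")]


def family_of(codon: str) -> tuple[str, ...]:
    """Synonymous family (tuple of RNA codons) containing *codon*."""
    aa = amino_acid(codon)
    if aa == "*":
        raise ValueError(f"{codon} is a stop codon; no synonymous family")
    return FAMILIES[aa]


def dna_to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def rna_to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


@lru_cache(maxsize=None)
def _sorted_by_degeneracy() -> tuple[str, ...]:
    return tuple(
        sorted(SENSE_CODONS, key=lambda c: (-len(family_of(c)), c))
    )


def degeneracy_order(codons) -> list[str]:
    """Order codons by descending family size, then alphabetically."""
    rank = {c: i for i, c in enumerate(_sorted_by_degeneracy())}
    return sorted(codons, key=lambda c: rank[dna_to_rna(c)])


def translate(dna: str) -> str:
    """Translate framed DNA (length divisible by 3) under table 5."""
    if len(dna) % 3:
        raise ValueError("sequence length not divisible by 3")
    rna = dna_to_rna(dna)
    return "".join(CODON_TABLE[rna[i : i + 3]] for i in range(0, len(rna), 3))
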