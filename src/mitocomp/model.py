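"""Core domain objects shared by every pipeline stage.

A :class:`MitoGenome` is an annotated circular DNA molecule stored on the
majority (J) strand; each annotated gene is a :class:`GeneFeature` with
1-based inclusive coordinates, GenBank-style.  Features that span the
circular origin carry ``wraps_origin=True`` and keep ``start > end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

VALID_KINDS = ("PCG", "tRNA", "rRNA", "CR", "spacer")
VALID_STRANDS = ("J", "N")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """One annotated gene on the J strand of a circular mitogenome.

    Parameters
    ----------
    name:
        Canonical gene symbol (``ND1``..``ND6``, ``ND4L``, ``COI``-``COIII``,
        ``ATP6``, ``ATP8``, ``CYTB``, ``trnX`` with isotype tag such as
        ``trnS^AGN``, ``rrnL``, ``rrnS``, ``CR``) or a raw name for
        unrecognised features.
    kind:
        One of ``PCG``, ``tRNA``, ``rRNA``, ``CR``, ``spacer``.
    start, end:
        1-based inclusive coordinates on the J strand.  ``start > end`` is
        only legal together with ``wraps_origin``.
    strand:
        ``J`` (majority) or ``N`` (minority); the sense strand of the gene.
    codon_start:
        Reading-frame offset 0-2 (protein-coding genes only).
    structure:
        Optional dot-bracket secondary structure (tRNA genes), given in
        sense-strand orientation.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str = "J"
    codon_start: int | None = None
    structure: str | None = None
    wraps_origin: bool = False
    inferred: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.kind == "PCG" and self.codon_start is None:
            self.codon_start = 0
        if self.codon_start is not None and self.codon_start not in (0, 1, 2):
            raise ValueError(f"codon_start must be 0-2, got {self.codon_start}")
        if self.start > self.end and not self.wraps_origin:
            raise ValueError(
                f"feature {self.name}: start {self.start} > end {self.end} "
                "without wraps_origin"
            )

    def length(self, genome_length: int | None = None) -> int:
        if self.wraps_origin:
            if genome_length is None:
                raise ValueError("genome length required for wrapping feature")
            return (genome_length - self.start + 1) + self.end
        return self.end - self.start + 1

    def copy(self, **changes) -> "GeneFeature":
        return replace(self, **changes)


@dataclass
class MitoGenome:
    """Annotated circular mitochondrial genome on the majority (J) strand."""

    identifier: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    is_circular: bool = True
    taxon_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
        self.validate()

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = len(self.sequence)
        names: dict[str, int] = {}
        n_cr = 0
        for f in self.features:
            if not (1 <= f.start <= n and 1 <= f.end <= n):
                raise ValueError(
                    f"feature {f.name} [{f.start},{f.end}] outside genome of length {n}"
                )
            if f.wraps_origin and not self.is_circular:
                raise ValueError(f"feature {f.name} wraps origin of a linear genome")
            if f.kind in ("PCG", "tRNA", "rRNA", "CR"):
                names[f.name] = names.get(f.name, 0) + 1
            if f.kind == "CR":
                n_cr += 1
        dupes = sorted(k for k, v in names.items() if v > 1)
        if dupes:
            raise ValueError(f"duplicate canonical gene names: {dupes}")
        if n_cr > 1:
            raise ValueError("at most one control region per genome")

    # -- lookups -----------------------------------------------------------
    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"{self.identifier}: no feature named {name!r}")

    def features_of_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)
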