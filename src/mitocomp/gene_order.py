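"""Gene orders as signed circular permutations and one-step
tandem-duplication-random-loss (TDRL) reasoning.

Under the TDRL model a contiguous block of genes is duplicated in tandem
and one copy of each duplicated gene is subsequently lost at random; the
surviving copies determine the derived order.  This is the mechanism
invoked for the Ditrysia trnM-trnI-trnQ cluster, which derives from the
ancestral insect trnI-trnQ-trnM arrangement by duplicating the I-Q-M
block and losing the first copies of trnI and trnQ and the second copy
of trnM.  TDRL preserves gene orientation, so strand-differing inputs
are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .model import MitoGenome
from .references import genes_37

DEFAULT_ANCHOR = "COI"

Gene = tuple[str, str]  # (canonical name, strand)


@dataclass(frozen=True)
class GeneOrderSignature:
    """Rotation-normalised signed circular gene order.

    ``genes`` starts at the anchor gene; two signatures of the same
    circular arrangement are therefore equal regardless of where the
    sequence record happened to be opened.
    """

    genes: tuple[Gene, ...]
    anchor: str = DEFAULT_ANCHOR

    def __post_init__(self) -> None:
        names = [g for g, _ in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in order")
        if self.genes and self.genes[0][0] != self.anchor:
            object.__setattr__(self, "genes", _rotate_to(self.genes, self.anchor))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genes)

    def strand_of(self, name: str) -> str:
        for g, s in self.genes:
            if g == name:
                return s
        raise KeyError(name)


def _rotate_to(genes: tuple[Gene, ...], anchor: str) -> tuple[Gene, ...]:
    names = [g for g, _ in genes]
    if anchor not in names:
        raise ValueError(f"anchor gene {anchor!r} absent from order")
    k = names.index(anchor)
    return genes[k:] + genes[:k]


def order_signature(genome: MitoGenome, anchor: str = DEFAULT_ANCHOR) -> GeneOrderSignature:
    """Signature of an annotated genome: genes sorted by start coordinate,
    rotation-normalised to the anchor.  CR and spacers are excluded."""
    genes = sorted((f for f in genome.features
                    if f.kind in ("PCG", "tRNA", "rRNA")),
                   key=lambda f: (f.start, f.end))
    return GeneOrderSignature(tuple((f.name, f.strand) for f in genes),
                              anchor=anchor)


def reference_signature(order_name: str, anchor: str = DEFAULT_ANCHOR) -> GeneOrderSignature:
    return GeneOrderSignature(genes_37(order_name), anchor=anchor)


def compare_orders(a: GeneOrderSignature, b: GeneOrderSignature
                   ) -> tuple[bool, list[tuple[int, int]]]:
    """Compare two circular orders over the same gene set.

    Returns ``(identical, segments)`` where segments are maximal runs of
    positions (0-based, in *a*'s anchored coordinates) at which the two
    orders differ, after the rotation of *b* minimising the number of
    differing positions.
    """
    if set(a.names) != set(b.names):
        diff = set(a.names) ^ set(b.names)
        raise ValueError(f"gene sets differ: {sorted(diff)}")
    n = len(a.genes)
    best_diffs: list[int] | None = None
    for k in range(n):
        rotated = b.genes[k:] + b.genes[:k]
        diffs = [i for i in range(n) if a.genes[i] != rotated[i]]
        if best_diffs is None or len(diffs) < len(best_diffs):
            best_diffs = diffs
    assert best_diffs is not None
    segments: list[tuple[int, int]] = []
    for i in best_diffs:
        if segments and i == segments[-1][1] + 1:
            segments[-1] = (segments[-1][0], i)
        else:
            segments.append((i, i))
    return (not best_diffs, segments)


# ---------------------------------------------------------------------------
# TDRL


@dataclass(frozen=True)
class TdrlEvent:
    """One tandem-duplication-random-loss event on a circular order.

    ``duplicated_block`` is the tuple of gene names duplicated (in source
    order); ``losses`` records, for each duplicated gene, which copy
    (1 = first, 2 = second) was deleted.  ``trivial`` marks events that
    reproduce the source order (all losses from the same copy).
    """

    duplicated_block: tuple[str, ...]
    losses: frozenset[tuple[int, str]]
    trivial: bool = False

    def kept_copies(self) -> dict[str, int]:
        lost = dict((g, c) for c, g in self.losses)
        return {g: 3 - lost[g] for g in self.duplicated_block}


def apply_tdrl(order: tuple[Gene, ...], start: int, block_len: int,
               losses: frozenset[tuple[int, str]]) -> tuple[Gene, ...]:
    """Replay a TDRL event on a circular order.

    ``start`` indexes the first duplicated gene; the block may wrap the
    origin.  The result is linearised with the surviving copies first,
    followed by the untouched genes in circular order — callers compare
    circularly.
    """
    n = len(order)
    block = [order[(start + k) % n] for k in range(block_len)]
    if {g for _, g in losses} != {name for name, _ in block} or \
            len(losses) != block_len:
        raise ValueError("losses must remove exactly one copy of each "
                         "duplicated gene")
    dup = [g for copy in (1, 2) for g in block if (copy, g[0]) not in losses]
    rest = [order[(start + block_len + k) % n] for k in range(n - block_len)]
    return tuple(dup + rest)


def _circular_equal(a: tuple[Gene, ...], b: tuple[Gene, ...]) -> bool:
    if len(a) != len(b):
        return False
    if not a:
        return True
    anchor = a[0]
    for k in range(len(b)):
        if b[k] == anchor and b[k:] + b[:k] == a:
            return True
    return False


def tdrl_explanations(source: GeneOrderSignature, target: GeneOrderSignature,
                      max_block: int = 3) -> list[TdrlEvent]:
    """Enumerate all one-step TDRL events turning *source* into *target*.

    Every contiguous block of length <= ``max_block`` (circularly) and
    every loss pattern keeping exactly one copy per duplicated gene is
    tried; each returned event is verified by replay.  An empty list means
    no one-step explanation exists at this block size.  Events that leave
    the order unchanged are returned (with ``trivial=True``) only when
    source equals target.
    """
    if set(source.names) != set(target.names):
        raise ValueError("gene sets differ")
    for name in source.names:
        if source.strand_of(name) != target.strand_of(name):
            raise ValueError(
                f"strand of {name} differs between orders; TDRL preserves "
                "orientation")
    src = source.genes
    tgt = target.genes
    n = len(src)
    events: list[TdrlEvent] = []
    seen: set[tuple] = set()
    for start in range(n):
        for block_len in range(1, min(max_block, n) + 1):
            block = tuple(src[(start + k) % n][0] for k in range(block_len))
            for pattern in product((1, 2), repeat=block_len):
                losses = frozenset(zip(pattern, block))
                result = apply_tdrl(src, start, block_len, losses)
                if _circular_equal(result, tgt):
                    trivial = len(set(pattern)) == 1
                    key = (block, losses)
                    if key in seen:
                        continue
                    seen.add(key)
                    events.append(TdrlEvent(block, losses, trivial=trivial))
    events.sort(key=lambda e: (len(e.duplicated_block), e.duplicated_block,
                               sorted(e.losses)))
    return events
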