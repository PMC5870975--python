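"""Independent brute-force oracles used by the test suite.

Each routine recomputes a quantity by the most direct method available
(exhaustive recursion, sliding comparison, literal replay) and stays
independent of the implementation paths it checks.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def nw_score_exhaustive(a: str, b: str, match: int, mismatch: int,
                        gap: int) -> int:
    """Global alignment score by plain memoised recursion."""

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> int:
        if i == 0:
            return gap * j
        if j == 0:
            return gap * i
        s = match if a[i - 1] == b[j - 1] else mismatch
        return max(f(i - 1, j - 1) + s, f(i - 1, j) + gap, f(i, j - 1) + gap)

    return f(len(a), len(b))


def codon_tally(sense_seq: str, codon_start: int) -> dict[str, int]:
    """3-mer stepping census of one framed CDS, terminator excluded,
    RNA alphabet.  Internal UAA/UAG are skipped (the census warns on
    them and excludes them from the sense count)."""
    seq = sense_seq[codon_start:].upper().replace("T", "U")
    counts: dict[str, int] = {}
    ncod = len(seq) // 3
    codons = [seq[3 * i: 3 * i + 3] for i in range(ncod)]
    if len(seq) % 3 == 0 and codons and codons[-1] in ("UAA", "UAG"):
        codons = codons[:-1]
    for c in codons:
        if c in ("UAA", "UAG"):
            continue
        counts[c] = counts.get(c, 0) + 1
    return counts


def motif_slide(region: str, pattern: str) -> list[tuple[int, int]]:
    """All 1-based spans where an IUPAC pattern matches, by literal
    sliding comparison."""
    hits = []
    k = len(pattern)
    for i in range(len(region) - k + 1):
        ok = True
        for p, t in zip(pattern, region[i: i + k]):
            if t not in IUPAC_SETS[p]:
                ok = False
                break
        if ok:
            hits.append((i + 1, i + k))
    return hits


def tdrl_all_events(source: tuple, target: tuple, max_block: int
                    ) -> set[tuple]:
    """Exhaustive one-step TDRL enumeration by literal replay.

    Orders are tuples of (name, strand).  Returns the set of
    (block names, frozenset of (copy, gene) losses) whose replay equals
    the target circularly.
    """
    n = len(source)

    def rotations(order):
        return [order[k:] + order[:k] for k in range(len(order))]

    target_rots = set(rotations(tuple(target)))
    found = set()
    for start in range(n):
        for length in range(1, min(max_block, n) + 1):
            block = [source[(start + k) % n] for k in range(length)]
            names = tuple(g for g, _ in block)
            for pattern in product((1, 2), repeat=length):
                # write out both tandem copies, then delete the lost ones
                tandem = [(1, g) for g in block] + [(2, g) for g in block]
                losses = frozenset(zip(pattern, names))
                survivors = [g for copy, g in tandem
                             if (copy, g[0]) not in losses]
                rest = [source[(start + length + k) % n]
                        for k in range(n - length)]
                if tuple(survivors + rest) in target_rots:
                    found.add((names, losses))
    return found
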