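"""Deterministic pairwise and center-star multiple alignment.

The package carries its own aligner so that every downstream statistic
(tRNA conservation, conserved-block discovery, supermatrix construction)
is reproducible bit-for-bit without external alignment software.

``global_align`` is Needleman–Wunsch with linear gap costs and a fixed
tie-break (diagonal, then up, then left).  ``center_star_msa`` picks the
sequence with the greatest summed pairwise score as the center and merges
the pairwise alignments under "once a gap, always a gap".
``local_align`` is Smith–Waterman with affine gap costs, used for the
spacer-versus-gene similarity scan.

The default scoring scheme is match +1, mismatch -1, gap -2 (linear); the
local aligner defaults to gap open -2, extend -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_SCORES = (1, -1, -2)


@dataclass
class Alignment:
    taxa: list[str]
    rows: list[str]
    score: float | None = None

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def columns(self):
        return ("".join(r[j] for r in self.rows) for j in range(self.n_columns))


def _nw_matrix(a: str, b: str, match: int, mismatch: int, gap: int) -> np.ndarray:
    """Full NW score matrix.  Rows are vectorised: with linear gaps the
    in-row (left) dependency reduces to a running maximum of
    ``candidate[j] - gap*j``."""
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    H[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], match, mismatch)
        cand = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + gap)
        d = np.empty(m + 1, dtype=np.int64)
        d[0] = gap * i
        d[1:] = cand - gap * np.arange(1, m + 1)
        H[i, :] = np.maximum.accumulate(d) + gap * np.arange(m + 1)
    return H


def global_align(a: str, b: str, scores: tuple[int, int, int] = DEFAULT_SCORES,
                 ids: tuple[str, str] = ("seq1", "seq2")) -> Alignment:
    """Optimal global (Needleman–Wunsch) alignment of two sequences.

    Ties are broken deterministically: diagonal, then up (gap in *b*),
    then left (gap in *a*).
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    match, mismatch, gap = scores
    H = _nw_matrix(a, b, match, mismatch, gap)
    i, j = len(a), len(b)
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                ra.append(a[i - 1]); rb.append(b[j - 1])
                i -= 1; j -= 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + gap:
            ra.append(a[i - 1]); rb.append("-")
            i -= 1
            continue
        ra.append("-"); rb.append(b[j - 1])
        j -= 1
    return Alignment(list(ids), ["".join(reversed(ra)), "".join(reversed(rb))],
                     score=float(H[len(a), len(b)]))


def global_score(a: str, b: str, scores: tuple[int, int, int] = DEFAULT_SCORES) -> int:
    match, mismatch, gap = scores
    return int(_nw_matrix(a, b, match, mismatch, gap)[len(a), len(b)])


# ---------------------------------------------------------------------------
# center-star MSA


def _merge(master_center: str, rows: list[str], pair_center: str,
           pair_other: str) -> tuple[str, list[str], str]:
    """Merge one pairwise alignment (center vs other) into the running MSA.

    Gap columns are reconciled "once a gap, always a gap": a gap introduced
    in the center by either alignment is propagated to all rows.
    """
    out_center: list[str] = []
    out_rows: list[list[str]] = [[] for _ in rows]
    out_other: list[str] = []
    i = j = 0  # i -> master columns, j -> pairwise columns
    nm, np_ = len(master_center), len(pair_center)
    while i < nm or j < np_:
        mc = master_center[i] if i < nm else None
        pc = pair_center[j] if j < np_ else None
        if mc is not None and pc is not None and mc != "-" and pc != "-":
            out_center.append(mc)
            for r, row in enumerate(rows):
                out_rows[r].append(row[i])
            out_other.append(pair_other[j])
            i += 1; j += 1
        elif mc == "-":
            out_center.append("-")
            for r, row in enumerate(rows):
                out_rows[r].append(row[i])
            out_other.append("-")
            i += 1
        else:  # pc == '-' (insertion in the new sequence)
            out_center.append("-")
            for r in range(len(rows)):
                out_rows[r].append("-")
            out_other.append(pair_other[j])
            j += 1
    return ("".join(out_center), ["".join(r) for r in out_rows],
            "".join(out_other))


def center_star_msa(seqs: list[str], scores: tuple[int, int, int] = DEFAULT_SCORES,
                    ids: list[str] | None = None) -> Alignment:
    """Center-star multiple alignment, deterministic under fixed input order.

    The center is the sequence maximising its summed pairwise NW score to
    all others (ties: lowest input index).  The reported score is that sum.
    """
    if len(seqs) < 2:
        raise ValueError("center_star_msa requires at least 2 sequences")
    if ids is None:
        ids = [f"seq{i + 1}" for i in range(len(seqs))]
    n = len(seqs)
    pair = {}
    sums = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            s = global_score(seqs[i], seqs[j], scores)
            pair[(i, j)] = s
            sums[i] += s
            sums[j] += s
    center = max(range(n), key=lambda i: (sums[i], -i))
    master = seqs[center]
    merged_rows: list[str] = []
    order = [k for k in range(n) if k != center]
    for k in order:
        aln = global_align(seqs[center], seqs[k], scores)
        master, merged_rows, new_row = _merge(master, merged_rows,
                                              aln.rows[0], aln.rows[1])
        merged_rows.append(new_row)
    rows_by_input: list[str] = [""] * n
    rows_by_input[center] = master
    for pos, k in enumerate(order):
        rows_by_input[k] = merged_rows[pos]
    total = sum(pair[(min(center, k), max(center, k))] for k in order)
    return Alignment(list(ids), rows_by_input, score=float(total))


# ---------------------------------------------------------------------------
# local alignment (affine gaps)


@dataclass
class LocalAlignment:
    """Best local alignment of *query* against *subject*.

    Spans are 1-based inclusive in the respective input sequences; identity
    is matches over aligned columns (gap columns included in the
    denominator).
    """

    score: int
    identity: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    aligned_query: str = field(repr=False, default="")
    aligned_subject: str = field(repr=False, default="")


def local_align(query: str, subject: str, match: int = 1, mismatch: int = -1,
                gap_open: int = -2, gap_extend: int = -1) -> LocalAlignment:
    """Smith–Waterman with affine gap costs.

    ``gap_open`` is the cost of the first gap position, ``gap_extend`` of
    each further position.  Tie-break on traceback: diagonal, gap in
    subject, gap in query.
    """
    if not query or not subject:
        raise ValueError("local_align requires non-empty sequences")
    n, m = len(query), len(subject)
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject (up)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (left)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        qi = query[i - 1]
        Hi, Hi1, Ei, Ei1, Fi = H[i], H[i - 1], E[i], E[i - 1], F[i]
        for j in range(1, m + 1):
            e = max(Hi1[j] + gap_open, Ei1[j] + gap_extend)
            f = max(Hi[j - 1] + gap_open, Fi[j - 1] + gap_extend)
            s = match if qi == subject[j - 1] else mismatch
            h = max(0, Hi1[j - 1] + s, e, f)
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best, bi, bj = h, i, j
    if best == 0:
        return LocalAlignment(0, 0.0, (0, 0), (0, 0))
    # traceback from (bi, bj) until H == 0
    i, j = bi, bj
    aq: list[str] = []
    asub: list[str] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0:
                break
            s = match if query[i - 1] == subject[j - 1] else mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                aq.append(query[i - 1]); asub.append(subject[j - 1])
                i -= 1; j -= 1
                continue
            if H[i][j] == E[i][j]:
                state = "E"
                continue
            state = "F"
            continue
        if state == "E":
            aq.append(query[i - 1]); asub.append("-")
            if E[i][j] == E[i - 1][j] + gap_extend:
                i -= 1
                continue
            i -= 1
            state = "H"
            continue
        # state == 'F'
        aq.append("-"); asub.append(subject[j - 1])
        if F[i][j] == F[i][j - 1] + gap_extend:
            j -= 1
            continue
        j -= 1
        state = "H"
    aligned_q = "".join(reversed(aq))
    aligned_s = "".join(reversed(asub))
    matches = sum(1 for x, y in zip(aligned_q, aligned_s)
                  if x == y and x != "-")
    cols = len(aligned_q)
    return LocalAlignment(
        score=best,
        identity=matches / cols if cols else 0.0,
        query_span=(i + 1, bi),
        subject_span=(j + 1, bj),
        aligned_query=aligned_q,
        aligned_subject=aligned_s,
    )
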