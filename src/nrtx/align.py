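"""Deterministic global pairwise alignment with affine gap costs.

Similarity checking of redundant contigs needs a reproducible global
alignment with well-defined gap bookkeeping, so this module implements
the Gotoh three-state dynamic programme directly (integer scores, numpy
row recurrences) rather than shelling out to an external aligner.  The
left-gap state collapses to a running maximum because a gap, once open,
can only extend, which keeps every row fully vectorised.

Traceback is pointer-free and deterministic: score ties are resolved by
preferring the diagonal (match/mismatch) move, then the up move (gap in
the second sequence), then the left move.  Terminal gaps are reported as
overhangs, internal gap runs as gap blocks; identity is computed over
matched columns only (columns where both sequences have a base).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NEG_INF = np.int32(-(2**30))


@dataclass(frozen=True)
class AlignParams:
    """Affine scoring: a gap of length L costs gap_open + gap_extend * L."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


@dataclass(frozen=True)
class GapBlock:
    """A maximal run of gap columns strictly inside the alignment.

    ``side`` names the sequence that *lacks* the bases ("a" or "b");
    ``col_start`` is the 0-based alignment column where the run begins.
    """

    side: str
    col_start: int
    length: int


@dataclass(frozen=True)
class PairAlignment:
    """A global alignment of two contigs with its similarity evidence."""

    aligned_a: str
    aligned_b: str
    score: int
    identity: float
    matched_columns: int
    # number of nt by which one sequence extends past the other at each end
    overhang_a_start: int
    overhang_a_end: int
    overhang_b_start: int
    overhang_b_end: int
    gap_blocks: tuple[GapBlock, ...] = field(default_factory=tuple)

    @property
    def max_overhang(self) -> int:
        return max(
            self.overhang_a_start,
            self.overhang_a_end,
            self.overhang_b_start,
            self.overhang_b_end,
        )

    @property
    def max_internal_gap(self) -> int:
        return max((g.length for g in self.gap_blocks), default=0)


def pairwise_align(
    seq_a: str, seq_b: str, params: AlignParams = AlignParams()
) -> PairAlignment:
    """Globally align two nucleotide sequences (Needleman-Wunsch/Gotoh).

    End gaps are penalised like internal ones; they surface in the result
    as overhangs rather than gap blocks.  Swapping the arguments swaps
    the "a"/"b" labels but preserves score, identity and block lengths.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    n, m = len(a), len(b)
    po, pe = np.int32(params.gap_open), np.int32(params.gap_extend)

    # state matrices: Mm = a_i aligned to b_j; Iu = gap in b (consumes a,
    # "up" move); Il = gap in a (consumes b, "left" move)
    Mm = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    Iu = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    Il = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    Mm[0, 0] = 0
    j_idx = np.arange(1, m + 1, dtype=np.int32)
    Il[0, 1:] = po + pe * j_idx
    i_idx = np.arange(1, n + 1, dtype=np.int32)
    Iu[1:, 0] = po + pe * i_idx

    match, mismatch = np.int32(params.match), np.int32(params.mismatch)
    for i in range(1, n + 1):
        sub = np.where(a[i - 1] == b, match, mismatch).astype(np.int32)
        prev_best = np.maximum(np.maximum(Mm[i - 1], Iu[i - 1]), Il[i - 1])
        Mm[i, 1:] = prev_best[:-1] + sub
        Iu[i, 1:] = np.maximum(Mm[i - 1, 1:] + po + pe, Iu[i - 1, 1:] + pe)
        Iu[i, 0] = po + pe * i
        # left-gap state: Il[i,j] = max_{k<j} Mm[i,k] + po + pe*(j-k)
        cand = Mm[i, :-1] + po - pe * np.arange(m, dtype=np.int32)
        Il[i, 1:] = np.maximum.accumulate(cand) + pe * j_idx
        Il[i, 0] = NEG_INF

    aligned_a, aligned_b = _traceback(a, b, Mm, Iu, Il, params)
    score = int(max(Mm[n, m], Iu[n, m], Il[n, m]))
    return _summarise(aligned_a, aligned_b, score)


def _traceback(a, b, Mm, Iu, Il, params: AlignParams) -> tuple[str, str]:
    po, pe = params.gap_open, params.gap_extend
    i, j = len(a), len(b)
    # tie preference: diagonal (M), then up (Iu), then left (Il)
    vals = (Mm[i, j], Iu[i, j], Il[i, j])
    best = max(vals)
    state = next(k for k in range(3) if vals[k] == best)
    cols_a: list[str] = []
    cols_b: list[str] = []
    a_s = a.tobytes().decode()
    b_s = b.tobytes().decode()
    while i > 0 or j > 0:
        if state == 0:  # diagonal
            cols_a.append(a_s[i - 1])
            cols_b.append(b_s[j - 1])
            sub = params.match if a_s[i - 1] == b_s[j - 1] else params.mismatch
            target = Mm[i, j] - sub
            prev = (Mm[i - 1, j - 1], Iu[i - 1, j - 1], Il[i - 1, j - 1])
            state = next(k for k in range(3) if prev[k] == target)
            i -= 1
            j -= 1
        elif state == 1:  # up: consume a, gap in b
            cols_a.append(a_s[i - 1])
            cols_b.append("-")
            if i == 1 and j == 0:
                state = 0
            elif Mm[i - 1, j] + po + pe == Iu[i, j]:
                state = 0
            else:
                state = 1
            i -= 1
        else:  # left: consume b, gap in a
            cols_a.append("-")
            cols_b.append(b_s[j - 1])
            if j == 1 and i == 0:
                state = 0
            elif Mm[i, j - 1] + po + pe == Il[i, j]:
                state = 0
            else:
                state = 2
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return "".join(reversed(cols_a)), "".join(reversed(cols_b))


def _summarise(aligned_a: str, aligned_b: str, score: int) -> PairAlignment:
    arr_a = np.frombuffer(aligned_a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(aligned_b.encode(), dtype=np.uint8)
    gap = ord("-")
    gap_a = arr_a == gap
    gap_b = arr_b == gap
    both = ~gap_a & ~gap_b
    matched = int(both.sum())
    if matched == 0:
        identity = 0.0
    else:
        identity = float((arr_a[both] == arr_b[both]).sum()) / matched

    ncols = len(aligned_a)
    lead_a = _run_len(gap_b, 0, 1)  # b gapped at start -> a overhangs 5'
    tail_a = _run_len(gap_b, ncols - 1, -1)
    lead_b = _run_len(gap_a, 0, 1)
    tail_b = _run_len(gap_a, ncols - 1, -1)

    blocks: list[GapBlock] = []
    for side, gaps in (("a", gap_a), ("b", gap_b)):
        start = None
        for col in range(ncols):
            if gaps[col] and start is None:
                start = col
            elif not gaps[col] and start is not None:
                if start > 0:  # runs touching column 0 are terminal
                    blocks.append(GapBlock(side, start, col - start))
                start = None
        # a trailing run touches the alignment end: terminal, not a block
    blocks.sort(key=lambda g: (g.col_start, g.side))
    return PairAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        identity=identity,
        matched_columns=matched,
        overhang_a_start=lead_a,
        overhang_a_end=tail_a,
        overhang_b_start=lead_b,
        overhang_b_end=tail_b,
        gap_blocks=tuple(blocks),
    )


def _run_len(mask: np.ndarray, start: int, step: int) -> int:
    n = 0
    i = start
    while 0 <= i < len(mask) and mask[i]:
        n += 1
        i += step
    return n
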