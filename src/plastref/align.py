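"""Pairwise global and local nucleotide alignment with identity scoring.

This module is the computational substrate for every sequence comparison in
the toolkit: clustering candidates for probe design, locating gene regions
on a consensus, ranking database hits, and producing the pairwise alignments
that distance estimation consumes.

Both aligners are exact dynamic programmes (Needleman–Wunsch and
Smith–Waterman with Gotoh affine gaps) with a fixed, documented tie-breaking
rule so that every result is reproducible bit-for-bit: during traceback the
diagonal move is preferred, then the vertical move (gap in ``b``), then the
horizontal move (gap in ``a``); for local alignment the earliest maximal
cell in row-major order anchors the traceback.

``N`` is treated as a masked position, not evidence: it scores as a mismatch
against every base including another ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "AlignmentParams",
    "PairwiseAlignment",
    "LocalAlignment",
    "global_align",
    "local_align",
    "identity",
]

_ALPHABET = "ACGTN"
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(_ALPHABET):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

_NEG = -(2**30)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for pairwise alignment.

    A gap run of length ``k`` costs ``gap_open + (k - 1) * gap_extend``.
    Setting ``gap_extend == gap_open`` gives linear gap costs (each gap
    column costs ``gap_open``), which is the mode the brute-force test
    oracle enumerates.
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")
        if self.gap_open > self.gap_extend:
            raise ValueError(
                "gap_open must be <= gap_extend (opening at least as costly)"
            )

    @classmethod
    def linear(cls, match: int = 1, mismatch: int = -1, gap: int = -2) -> "AlignmentParams":
        """Linear gap costs: every gap column costs ``gap``."""
        return cls(match=match, mismatch=mismatch, gap_open=gap, gap_extend=gap)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped alignment of two nucleotide sequences.

    ``aligned_a`` and ``aligned_b`` have equal length (``n_columns``), no
    column is gap-in-both, and stripping gaps recovers the inputs.
    """

    aligned_a: str
    aligned_b: str
    score: int
    n_match: int = field(default=0)
    n_mismatch: int = field(default=0)
    n_columns: int = field(default=0)

    @staticmethod
    def from_strings(aligned_a: str, aligned_b: str, score: int) -> "PairwiseAlignment":
        if len(aligned_a) != len(aligned_b):
            raise ValueError("aligned strings differ in length")
        n_match = 0
        n_mismatch = 0
        for x, y in zip(aligned_a, aligned_b):
            if x == "-" or y == "-":
                continue
            if x == y and x != "N":
                n_match += 1
            else:
                n_mismatch += 1
        return PairwiseAlignment(
            aligned_a, aligned_b, score, n_match, n_mismatch, len(aligned_a)
        )

    @property
    def ungapped_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def ungapped_b(self) -> str:
        return self.aligned_b.replace("-", "")


@dataclass(frozen=True)
class LocalAlignment(PairwiseAlignment):
    """A local alignment plus its footprint on both inputs.

    Coordinates are 0-based half-open on the *ungapped* inputs; an empty
    alignment (no positive-scoring cell) has score 0 and empty footprints.
    """

    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes (A=0 C=1 G=2 T=3 N=4).

    Input gap characters are stripped first. Raises on empty input or on
    any character outside ``{A,C,G,T,N,-}`` (case-insensitive).
    """
    seq = seq.replace("-", "")
    if not seq:
        raise ValueError("empty input sequence")
    codes = _CODE[np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise ValueError(f"non-IUPAC character {bad!r} in sequence")
    return codes


# Traceback codes packed per cell in one uint8:
#   bits 0-1: H-state move (0 diag, 1 up/gap-in-b, 2 left/gap-in-a, 3 stop)
#   bit 2:    E (vertical) came from E above (gap extension) rather than H
#   bit 3:    F (horizontal) came from F at left rather than H
@njit(cache=True)
def _fill_global(a, b, match, mismatch, go, ge):  # pragma: no cover - jitted
    n = a.size
    m = b.size
    H = np.empty(m + 1, np.int64)
    E = np.empty(m + 1, np.int64)
    tb = np.zeros((n + 1, m + 1), np.uint8)
    H[0] = 0
    for j in range(1, m + 1):
        H[j] = go + (j - 1) * ge
        E[j] = _NEG
        tb[0, j] = 2 | 8  # left, F-extension
    tb[0, 1] = 2  # first gap column opens
    for i in range(1, n + 1):
        diag = H[0]
        H[0] = go + (i - 1) * ge
        tb[i, 0] = 1 | (4 if i > 1 else 0)
        f = _NEG
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai != 4) else mismatch
            e_ext = E[j] + ge
            e_open = H[j] + go
            if e_ext > e_open:
                e = e_ext
                ebit = 4
            else:
                e = e_open
                ebit = 0
            E[j] = e
            f_ext = f + ge
            f_open = H[j - 1] + go
            if f_ext > f_open:
                f = f_ext
                fbit = 8
            else:
                f = f_open
                fbit = 0
            d = diag + s
            diag = H[j]
            h = d
            t = 0
            if e > h:
                h = e
                t = 1
            if f > h:
                h = f
                t = 2
            H[j] = h
            tb[i, j] = t | ebit | fbit
    return H[m], tb


@njit(cache=True)
def _fill_local(a, b, match, mismatch, go, ge):  # pragma: no cover - jitted
    n = a.size
    m = b.size
    H = np.zeros(m + 1, np.int64)
    E = np.empty(m + 1, np.int64)
    tb = np.zeros((n + 1, m + 1), np.uint8)
    for j in range(m + 1):
        E[j] = _NEG
        tb[0, j] = 3
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        diag = 0
        H[0] = 0
        tb[i, 0] = 3
        f = _NEG
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai != 4) else mismatch
            e_ext = E[j] + ge
            e_open = H[j] + go
            if e_ext > e_open:
                e = e_ext
                ebit = 4
            else:
                e = e_open
                ebit = 0
            E[j] = e
            f_ext = f + ge
            f_open = H[j - 1] + go
            if f_ext > f_open:
                f = f_ext
                fbit = 8
            else:
                f = f_open
                fbit = 0
            d = diag + s
            diag = H[j]
            h = d
            t = 0
            if e > h:
                h = e
                t = 1
            if f > h:
                h = f
                t = 2
            if h <= 0:
                h = 0
                t = 3
            H[j] = h
            tb[i, j] = t | ebit | fbit
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, tb


_GAP = ord("-")
_BYTES = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)


@njit(cache=True)
def _traceback(tb, a, b, i, j, local):  # pragma: no cover - jitted
    # Returns reversed move list: 0 diag, 1 up (consume a), 2 left (consume b)
    moves = np.empty(i + j, np.uint8)
    k = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 or j > 0:
        if state == 0:
            t = tb[i, j] & 3
            if local and t == 3:
                break
            if not local:
                if i == 0:
                    t = 2
                elif j == 0:
                    t = 1
            if t == 0:
                moves[k] = 0
                k += 1
                i -= 1
                j -= 1
            else:
                state = t
        elif state == 1:
            moves[k] = 1
            k += 1
            ext = tb[i, j] & 4
            i -= 1
            state = 1 if ext else 0
            if i == 0 and not local:
                state = 0
        else:
            moves[k] = 2
            k += 1
            ext = tb[i, j] & 8
            j -= 1
            state = 2 if ext else 0
            if j == 0 and not local:
                state = 0
    return moves[:k], i, j


def _build_strings(a_codes, b_codes, moves, ai, bj):
    """Materialise aligned strings from reversed traceback moves."""
    out_a = []
    out_b = []
    i, j = ai, bj
    for mv in moves[::-1]:
        if mv == 0:
            out_a.append(_ALPHABET[a_codes[i]])
            out_b.append(_ALPHABET[b_codes[j]])
            i += 1
            j += 1
        elif mv == 1:
            out_a.append(_ALPHABET[a_codes[i]])
            out_b.append("-")
            i += 1
        else:
            out_a.append("-")
            out_b.append(_ALPHABET[b_codes[j]])
            j += 1
    return "".join(out_a), "".join(out_b), i, j


def global_align(a: str, b: str, params: AlignmentParams | None = None) -> PairwiseAlignment:
    """Optimal Needleman–Wunsch global alignment of ``a`` and ``b``.

    Deterministic: ties during traceback prefer the diagonal move, then the
    vertical move (gap in ``b``), then the horizontal move (gap in ``a``).
    """
    params = params or AlignmentParams()
    ca = encode(a)
    cb = encode(b)
    score, tb = _fill_global(
        ca, cb, params.match, params.mismatch, params.gap_open, params.gap_extend
    )
    moves, i0, j0 = _traceback(tb, ca, cb, ca.size, cb.size, False)
    aligned_a, aligned_b, _, _ = _build_strings(ca, cb, moves, i0, j0)
    return PairwiseAlignment.from_strings(aligned_a, aligned_b, int(score))


def local_align(a: str, b: str, params: AlignmentParams | None = None) -> LocalAlignment:
    """Optimal Smith–Waterman local alignment with footprint coordinates.

    The footprint is 0-based half-open on each (gap-stripped) input. When no
    cell scores positively the empty alignment is returned with score 0.
    """
    params = params or AlignmentParams()
    ca = encode(a)
    cb = encode(b)
    score, bi, bj, tb = _fill_local(
        ca, cb, params.match, params.mismatch, params.gap_open, params.gap_extend
    )
    if score <= 0:
        return LocalAlignment("", "", 0, 0, 0, 0, 0, 0, 0, 0)
    moves, i0, j0 = _traceback(tb, ca, cb, bi, bj, True)
    aligned_a, aligned_b, a_end, b_end = _build_strings(ca, cb, moves, i0, j0)
    base = PairwiseAlignment.from_strings(aligned_a, aligned_b, int(score))
    return LocalAlignment(
        base.aligned_a,
        base.aligned_b,
        base.score,
        base.n_match,
        base.n_mismatch,
        base.n_columns,
        i0,
        a_end,
        j0,
        b_end,
    )


def identity(aln: PairwiseAlignment, mode: str = "columns") -> float:
    """Fraction of matching positions in an alignment.

    ``mode='columns'`` divides matches by the number of alignment columns;
    ``mode='shorter'`` divides by the shorter ungapped sequence length, the
    convention greedy clustering uses for its identity threshold. For local
    alignments the ungapped lengths refer to the aligned footprint.
    """
    if aln.n_columns == 0:
        raise ValueError("zero-length alignment has no identity")
    if mode == "columns":
        return aln.n_match / aln.n_columns
    if mode == "shorter":
        shorter = min(len(aln.ungapped_a), len(aln.ungapped_b))
        return aln.n_match / shorter
    raise ValueError(f"unknown identity mode {mode!r}")
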