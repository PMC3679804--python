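"""Hamming-distance primitives and the all-pairs l-mer distance matrix.

The matrix between the (m-l+1) windows of two sequences can be filled
naively in O(m^2 l), or in O(m^2) by walking each diagonal: consecutive
windows share an (l-1)-length overlap, so the distance of the next cell
follows from the current one by comparing one leading and one trailing
character.  Diagonals where the second sequence's window starts before the
first's are reached by conceptually appending a copy of the second
sequence; here that wrap-around is realised with modular indexing, and the
cells that correspond to wrapped (non-existent) windows are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class LMerRef:
    """Locates an l-mer: sequence number and start offset, both 0-based."""

    seq_index: int
    offset: int
    length: int


@dataclass(frozen=True)
class DistanceMatrix:
    """(m-l+1) x (m-l+1) grid; rows index windows of s1, columns of si."""

    values: np.ndarray
    l: int  # noqa: E741

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        object.__setattr__(self, "values", v)


def hamming_lmer(x: str, y: str) -> int:
    """Number of positions at which two equal-length strings differ."""
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    return sum(a != b for a, b in zip(x, y))


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def window_distances(x: str, s: str | np.ndarray) -> np.ndarray:
    """Hamming distance of ``x`` against every window of ``s`` (vectorised)."""
    arr = _encode(s) if isinstance(s, str) else s
    l = len(x)
    if l > arr.size:
        raise ValueError(f"l-mer of length {l} longer than sequence ({arr.size})")
    wins = sliding_window_view(arr, l)
    return (wins != _encode(x)).sum(axis=1)


def min_distance_to_sequence(x: str, s: str) -> int:
    """min over windows of s of the Hamming distance to x."""
    return int(window_distances(x, s).min())


def distance_matrix_naive(s1: str, si: str, l: int) -> DistanceMatrix:
    """Direct O(m^2 l) evaluation of every window-pair distance."""
    if len(s1) != len(si):
        raise ValueError("sequences must have equal length")
    if l > len(s1) or l < 1:
        raise ValueError(f"invalid window length l={l} for m={len(s1)}")
    w1 = sliding_window_view(_encode(s1), l)
    w2 = sliding_window_view(_encode(si), l)
    vals = (w1[:, None, :] != w2[None, :, :]).sum(axis=2)
    return DistanceMatrix(vals.astype(np.int64), l)


def distance_matrix_diagonal(s1: str, si: str, l: int) -> DistanceMatrix:
    """O(m^2) diagonal-recurrence evaluation; equals the naive matrix.

    One full O(l) Hamming evaluation seeds the top of each of the m
    diagonals; every later cell is the previous cell minus the leading
    mismatch plus the trailing mismatch.  Modular indexing of ``si``
    stands in for appending a copy of it; running positions that fall in
    the wrapped zone are carried through the recurrence but not stored.
    """
    if len(s1) != len(si):
        raise ValueError("sequences must have equal length")
    m = len(s1)
    if l > m or l < 1:
        raise ValueError(f"invalid window length l={l} for m={m}")
    w = m - l + 1
    vals = [[0] * w for _ in range(w)]
    for c in range(m):
        # seed: distance of s1's first window to si's (mod-)window at c
        dist = sum(s1[t] != si[(c + t) % m] for t in range(l))
        if c < w:
            vals[0][c] = dist
        for a in range(1, w):
            e = c + a  # column in the doubled-sequence coordinate
            dist += (s1[a + l - 1] != si[(e + l - 1) % m]) - (
                s1[a - 1] != si[(e - 1) % m]
            )
            if e < w:
                vals[a][e] = dist
            elif e >= m:
                vals[a][e - m] = dist
            # w <= e < m: wrapped window, discarded
    return DistanceMatrix(np.array(vals, dtype=np.int64), l)
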