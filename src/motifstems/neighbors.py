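"""2d-neighbor discovery and candidate selection.

If a candidate l-mer x has no window within Hamming distance 2d in some
input sequence, then (by the triangle inequality) no d-neighbor of x can
be an (l, d)-motif, so x is skipped outright.  For a surviving x, stems
are generated only against the sequence in which x has the fewest
2d-neighbors (I_min): that sequence must still contain a motif occurrence
if x is within d of a motif, so pairing against it loses nothing while
minimising the number of pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .distance import distance_matrix_diagonal, window_distances
from .sequences import SequenceSet


def collect_2d_neighbors(x: str, s: str, d: int) -> list[int]:
    """Offsets j in s with HD(x, s[j:j+l]) <= 2d, ascending."""
    return [int(j) for j in np.flatnonzero(window_distances(x, s) <= 2 * d)]


@dataclass(frozen=True)
class NeighborMatrix:
    """Per (candidate l-mer of s1, other sequence) lists of 2d-neighbor offsets.

    ``entries[k][i-1]`` holds the ascending offsets of the 2d-neighbors of
    the k-th window of s1 inside sequence i (i = 1..n-1, 0-based with the
    candidate sequence at index 0).
    """

    entries: tuple[tuple[tuple[int, ...], ...], ...]
    l: int  # noqa: E741
    d: int


@dataclass(frozen=True)
class CandidateSelection:
    """Outcome of the skip/min-sequence rule for one candidate l-mer."""

    x_index: int
    status: Literal["viable", "skipped"]
    min_seq_index: int | None = None  # 0-based; always >= 1 when viable
    i_min: tuple[int, ...] = ()

    @property
    def skipped(self) -> bool:
        return self.status == "skipped"


def build_neighbor_matrix(seqs: SequenceSet, l: int, d: int) -> NeighborMatrix:
    """All 2d-neighbor lists of every s1 window, via the diagonal recurrence."""
    if l > seqs.m or l < 1:
        raise ValueError(f"invalid l={l} for m={seqs.m}")
    s1 = seqs.sequences[0]
    w = seqs.m - l + 1
    per_seq_rows = []
    for i in range(1, seqs.n):
        dm = distance_matrix_diagonal(s1, seqs.sequences[i], l)
        per_seq_rows.append(dm.values <= 2 * d)
    entries = tuple(
        tuple(
            tuple(int(j) for j in np.flatnonzero(per_seq_rows[i - 1][k]))
            for i in range(1, seqs.n)
        )
        for k in range(w)
    )
    return NeighborMatrix(entries=entries, l=l, d=d)


def select_candidate(x_index: int, matrix: NeighborMatrix) -> CandidateSelection:
    """Apply the skip rule, else pick the smallest neighbor list.

    Sequences are scanned in input order with early exit on the first
    empty list; ties on list size break to the lowest sequence index.
    """
    lists = matrix.entries[x_index]
    best_i: int | None = None
    best: tuple[int, ...] = ()
    for i, offsets in enumerate(lists, start=1):
        if not offsets:
            return CandidateSelection(x_index=x_index, status="skipped")
        if best_i is None or len(offsets) < len(best):
            best_i, best = i, offsets
    return CandidateSelection(
        x_index=x_index, status="viable", min_seq_index=best_i, i_min=best
    )
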