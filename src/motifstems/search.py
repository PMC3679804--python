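"""End-to-end stem search drivers and the brute-force motif oracle.

Three drivers share one contract — emit a set of wildcard stems whose
expansions form a superset of all (l, d)-motifs:

* ``mss1``: per candidate l-mer of s1, compute 2d-neighbor lists on the
  fly (O(m^2 n l) distance work, O(m) space), pair against I_min.
* ``mss2``: identical output, but neighbor lists come from the O(m^2 n)
  diagonal-recurrence matrix (O(m^2) space).
* ``stemming_baseline``: the earlier stemming approach — gather every
  l-mer of every sequence that is within 2d of all sequences into a set
  I, then place wildcards for every ordered pair of I at distance <= 2d.

The optional post-process retains a stem only if every sequence has a
window within distance d of it (wildcards matching freely).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from math import comb
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .distance import LMerRef, hamming_lmer, window_distances
from .neighbors import build_neighbor_matrix, collect_2d_neighbors, select_candidate
from .sequences import WILDCARD, SequenceSet
from .stems import PairContext, place_wildcards, stem_distance

Provenance = tuple[LMerRef, LMerRef]


class OracleInfeasibleError(RuntimeError):
    """The brute-force neighborhood enumeration would be too large."""


@dataclass(frozen=True)
class SearchParams:
    l: int  # noqa: E741
    d: int
    algorithm: Literal["mss1", "mss2", "stemming"] = "mss2"
    post_process: bool = False

    def validate(self, seqs: SequenceSet) -> None:
        if not 0 <= self.d <= self.l <= seqs.m:
            raise ValueError(
                f"need 0 <= d <= l <= m, got d={self.d}, l={self.l}, m={seqs.m}"
            )


@dataclass
class StemResult:
    """Deduplicated stems (lexicographic order) with provenance and counters."""

    stems: tuple[str, ...]
    provenance: dict[str, Provenance] = field(default_factory=dict)
    counters: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stems = tuple(sorted(set(self.stems)))


def _add_pair_stems(
    stems: dict[str, Provenance],
    x: str,
    x_ref: LMerRef,
    x_prime: str,
    xp_ref: LMerRef,
    d: int,
) -> None:
    ctx = PairContext.from_pair(x, x_prime)
    for pattern in place_wildcards(ctx, d):
        stems.setdefault(pattern, (x_ref, xp_ref))  # keep first provenance


def _finalize(
    stems: dict[str, Provenance],
    counters: dict[str, int],
    seqs: SequenceSet,
    params: SearchParams,
) -> StemResult:
    result = StemResult(
        stems=tuple(stems), provenance=dict(stems), counters=counters
    )
    if params.post_process:
        result = post_process(result, seqs, params)
    return result


def mss1(seqs: SequenceSet, params: SearchParams) -> StemResult:
    """Basic driver: neighbor lists recomputed per candidate, O(m) space."""
    params.validate(seqs)
    l, d = params.l, params.d
    s1 = seqs.sequences[0]
    stems: dict[str, Provenance] = {}
    counters = {"candidates": 0, "skipped": 0, "pairs": 0}
    for k in range(seqs.m - l + 1):
        counters["candidates"] += 1
        x = s1[k : k + l]
        best_i: int | None = None
        best: list[int] = []
        skipped = False
        for i in range(1, seqs.n):  # input order, early exit on empty
            offs = collect_2d_neighbors(x, seqs.sequences[i], d)
            if not offs:
                skipped = True
                break
            if best_i is None or len(offs) < len(best):
                best_i, best = i, offs
        if skipped:
            counters["skipped"] += 1
            continue
        x_ref = LMerRef(0, k, l)
        si = seqs.sequences[best_i]
        for j in best:
            counters["pairs"] += 1
            _add_pair_stems(stems, x, x_ref, si[j : j + l], LMerRef(best_i, j, l), d)
    return _finalize(stems, counters, seqs, params)


def mss2(seqs: SequenceSet, params: SearchParams) -> StemResult:
    """Speedup driver: one materialised neighbor matrix, same stem set."""
    params.validate(seqs)
    l, d = params.l, params.d
    s1 = seqs.sequences[0]
    matrix = build_neighbor_matrix(seqs, l, d)
    stems: dict[str, Provenance] = {}
    counters = {"candidates": 0, "skipped": 0, "pairs": 0}
    for k in range(seqs.m - l + 1):
        counters["candidates"] += 1
        sel = select_candidate(k, matrix)
        if sel.skipped:
            counters["skipped"] += 1
            continue
        x = s1[k : k + l]
        x_ref = LMerRef(0, k, l)
        si = seqs.sequences[sel.min_seq_index]
        for j in sel.i_min:
            counters["pairs"] += 1
            _add_pair_stems(
                stems, x, x_ref, si[j : j + l], LMerRef(sel.min_seq_index, j, l), d
            )
    return _finalize(stems, counters, seqs, params)


def stemming_baseline(seqs: SequenceSet, params: SearchParams) -> StemResult:
    """The earlier stemming algorithm: stems from every pair of the I set.

    I holds each l-mer (of any sequence) whose distance to every sequence
    is <= 2d; stems come from every ordered pair of I members at mutual
    distance <= 2d, including identical pairs.
    """
    params.validate(seqs)
    l, d = params.l, params.d
    refs: list[tuple[str, LMerRef]] = []
    seen: set[str] = set()
    for i, s in enumerate(seqs.sequences):
        for j in range(seqs.m - l + 1):
            x = s[j : j + l]
            if x in seen:
                continue
            if all(
                int(window_distances(x, sp).min()) <= 2 * d for sp in seqs.sequences
            ):
                seen.add(x)
                refs.append((x, LMerRef(i, j, l)))
    stems: dict[str, Provenance] = {}
    counters = {"candidates": len(refs), "skipped": 0, "pairs": 0}
    for x, x_ref in refs:
        for y, y_ref in refs:
            if hamming_lmer(x, y) <= 2 * d:
                counters["pairs"] += 1
                _add_pair_stems(stems, x, x_ref, y, y_ref, d)
    return _finalize(stems, counters, seqs, params)


def post_process(
    result: StemResult, seqs: SequenceSet, params: SearchParams
) -> StemResult:
    """Retain a stem only if every sequence has a window within distance d."""
    d = params.d
    encoded = seqs.encoded()
    views = [sliding_window_view(e, params.l) for e in encoded]
    wc = ord(WILDCARD)
    kept: dict[str, Provenance] = {}
    for pattern in result.stems:
        enc = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
        mask = enc != wc
        ok = True
        for wins in views:
            dist = (wins[:, mask] != enc[mask]).sum(axis=1)
            if int(dist.min(initial=params.l)) > d:
                ok = False
                break
        if ok:
            kept[pattern] = result.provenance.get(
                pattern, (LMerRef(0, 0, params.l), LMerRef(0, 0, params.l))
            )
    counters = dict(result.counters)
    counters["removed_by_post_process"] = len(result.stems) - len(kept)
    return StemResult(stems=tuple(kept), provenance=kept, counters=counters)


def _neighborhood_size(l: int, d: int, sigma: int) -> int:
    return sum(comb(l, i) * (sigma - 1) ** i for i in range(d + 1))


def pms_oracle(
    seqs: SequenceSet, params: SearchParams, max_work: int = 5_000_000
) -> list[str]:
    """Exact (l, d)-motif set by brute force (test oracle, small scale only).

    Enumerates the d-neighborhood of every window of s1 (any motif must be
    within d of some s1 window) and keeps candidates within d of every
    sequence.  Raises :class:`OracleInfeasibleError` when the candidate
    count estimate exceeds ``max_work``.
    """
    params.validate(seqs)
    l, d = params.l, params.d
    sigma = seqs.sigma
    est = (seqs.m - l + 1) * _neighborhood_size(l, d, sigma)
    if est > max_work:
        raise OracleInfeasibleError(
            f"~{est} candidate l-mers exceeds the work limit {max_work}"
        )
    s1 = seqs.sequences[0]
    candidates: set[str] = set()
    for k in range(seqs.m - l + 1):
        x = s1[k : k + l]
        for r in range(d + 1):
            for positions in combinations(range(l), r):
                alts = [
                    [c for c in seqs.alphabet if c != x[p]] for p in positions
                ]
                for fill in product(*alts):
                    y = list(x)
                    for p, c in zip(positions, fill):
                        y[p] = c
                    candidates.add("".join(y))
    encoded = seqs.encoded()
    motifs = [
        y
        for y in candidates
        if all(int(window_distances(y, e).min()) <= d for e in encoded)
    ]
    return sorted(motifs)
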