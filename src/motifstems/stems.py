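"""Wildcard stems: placement between an l-mer pair, semantics, counting.

A stem is an l-length pattern over the alphabet plus a wildcard character;
it represents the set of l-mers obtained by substituting each wildcard
with any alphabet character.  Given a pair (x, x') at Hamming distance
d_x <= 2d, stems are built from x by replacing i positions of the
non-matching region and k positions of the matching region with
wildcards, where

    d_x <= d:  0 <= i <= d_x,          k = d - max(i, d_x - i)
    d_x  > d:  d_x - d <= i <= d,      k = d - max(i, d_x - i)

Only the maximal matching-region count k is enumerated: a stem with fewer
matching-region wildcards is covered by one with the full k, so emitting
it would only inflate the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from math import comb

from .sequences import WILDCARD


@dataclass(frozen=True)
class Stem:
    """An l-length pattern over alphabet + wildcard."""

    pattern: str

    @property
    def wildcard_count(self) -> int:
        return self.pattern.count(WILDCARD)

    @property
    def l(self) -> int:  # noqa: E743
        return len(self.pattern)


@dataclass(frozen=True)
class PairContext:
    """An l-mer pair with its matching/non-matching position partition."""

    x: str
    x_prime: str
    matching_positions: frozenset[int]
    nonmatching_positions: frozenset[int]
    d_x: int

    @classmethod
    def from_pair(cls, x: str, x_prime: str) -> "PairContext":
        if len(x) != len(x_prime):
            raise ValueError("pair members must have equal length")
        non = frozenset(i for i in range(len(x)) if x[i] != x_prime[i])
        return cls(
            x=x,
            x_prime=x_prime,
            matching_positions=frozenset(range(len(x))) - non,
            nonmatching_positions=non,
            d_x=len(non),
        )


def wildcard_budget(d_x: int, d: int) -> list[tuple[int, int]]:
    """Admissible (i, k) wildcard counts for the non-matching/matching regions.

    Rejects d_x > 2d: such a pair admits no common d-neighbor and should
    never reach stem generation.
    """
    if d_x < 0 or d < 0:
        raise ValueError("d_x and d must be non-negative")
    if d_x > 2 * d:
        raise ValueError(f"pair distance d_x={d_x} exceeds 2d={2 * d}")
    lo = 0 if d_x <= d else d_x - d
    hi = min(d_x, d)
    return [(i, d - max(i, d_x - i)) for i in range(lo, hi + 1)]


def place_wildcards(ctx: PairContext, d: int) -> set[str]:
    """All stems for the pair: every placement of each (i, k) budget entry."""
    non = sorted(ctx.nonmatching_positions)
    mat = sorted(ctx.matching_positions)
    stems: set[str] = set()
    base = list(ctx.x)
    for i, k in wildcard_budget(ctx.d_x, d):
        for non_pick in combinations(non, i):
            for mat_pick in combinations(mat, k):
                pattern = base.copy()
                for pos in non_pick + mat_pick:
                    pattern[pos] = WILDCARD
                stems.add("".join(pattern))
    return stems


def count_stems_exact(l: int, d_x: int, d: int) -> int:
    """Closed-form stem count for a pair at distance d_x: sum of
    C(d_x, i) * C(l - d_x, k) over the wildcard budget."""
    if not 0 <= d_x <= 2 * d or 2 * d > 2 * l or d_x > l:
        raise ValueError(f"invalid (l={l}, d_x={d_x}, d={d})")
    return sum(comb(d_x, i) * comb(l - d_x, k) for i, k in wildcard_budget(d_x, d))


def expand_stem(stem: str | Stem, alphabet: str) -> set[str]:
    """The sigma^(#wildcards) l-mers a stem represents."""
    pattern = stem.pattern if isinstance(stem, Stem) else stem
    slots = [i for i, c in enumerate(pattern) if c == WILDCARD]
    out = set()
    base = list(pattern)
    for fill in product(alphabet, repeat=len(slots)):
        for pos, c in zip(slots, fill):
            base[pos] = c
        out.add("".join(base))
    return out


def stem_distance(stem: str | Stem, y: str) -> int:
    """Mismatches between stem and y over non-wildcard positions.

    Equals the minimum Hamming distance from y to any member of the
    stem's expansion (wildcards match for free).
    """
    pattern = stem.pattern if isinstance(stem, Stem) else stem
    if len(pattern) != len(y):
        raise ValueError("length mismatch")
    return sum(a != b and a != WILDCARD for a, b in zip(pattern, y))
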