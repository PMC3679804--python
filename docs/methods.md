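# Methods

## Problem and model

Input: a set S of n sequences of common length m over an alphabet Σ of size
σ, plus integers l and d. An (l, d)-motif is an l-mer whose distance to
every sequence (minimum Hamming distance over the sequence's m−l+1 windows)
is at most d. Stem search returns l-length patterns over Σ ∪ {`*`} whose
expansions (every substitution of the wildcards) form a superset of all
(l, d)-motifs. Coordinates are 0-based and half-open throughout.

## Candidate pruning

Candidates are the l-mers of the first sequence only. Two facts drive the
pruning, both consequences of the triangle inequality for Hamming distance:

1. **Skip rule.** If two l-mers are more than 2d apart, no third l-mer is
   within d of both. Hence if candidate x has no window within 2d in some
   sequence, no d-neighbor of x can be a motif and x is dropped. (Verified
   exhaustively for binary strings of length ≤ 5 in the test suite.)
2. **I_min restriction.** If a motif y is within d of x, then every
   sequence's occurrence of y is within 2d of x, i.e. appears in x's
   2d-neighbor list for that sequence. Pairing x against the *smallest*
   such list therefore loses no motif while minimising pair work.

## Wildcard placement

For a pair (x, x′) at Hamming distance d_x ≤ 2d, stems are built from x by
wildcarding i positions of the non-matching region (where x and x′ differ)
and k positions of the matching region:

- d_x ≤ d:  i ∈ {0, …, d_x}
- d_x > d:  i ∈ {d_x − d, …, d}
- in both cases k = d − max(i, d_x − i)

Wildcards always count as mismatches against x; against x′ they are free in
the non-matching region (they erase an existing mismatch) and count in the
matching region. The bound k keeps both tallies ≤ d: i + k ≤ d versus x and
(d_x − i) + k ≤ d versus x′. Only the maximal k is enumerated — any stem
with fewer matching-region wildcards is covered by one with the full k, so
emitting it would only enlarge the output. The resulting closed-form count
per pair is Σ_i C(d_x, i)·C(l − d_x, k), which the tests check against full
enumeration for all l ≤ 12, d ≤ 4. The *coverage lemma* — every y within d
of both pair members is matched by some generated stem — is checked
exhaustively for l ≤ 6, σ ≤ 4, d ≤ 2; exhaustion over pairs uses the fact
that placement is equivariant under position permutations and per-position
alphabet relabelings (itself unit-tested), so pairs reduce to the canonical
form x = A^l, x′ = B^{d_x} A^{l−d_x} once σ^l grows past direct enumeration.

Stems are deduplicated by exact pattern string; expansions that are nested
across distinct patterns are not merged (no principled merging rule exists
without re-deriving the motif set). The wildcard is `*` and is rejected as
an alphabet character.

## Distance matrices: naive and diagonal

mss1 recomputes window distances per candidate (O(m²nl) time, O(m) space).
mss2 materialises, per sequence pair, the full (m−l+1)² matrix in O(m²):
consecutive cells along a diagonal differ only by the leading character
leaving the window and the trailing character entering it, so one O(l) seed
per diagonal plus an O(1) update per cell suffices. Diagonals on which the
second sequence's window would start before the first's are reached by
conceptually appending a copy of the second sequence — implemented as
modular indexing — and the cells corresponding to wrapped, non-existent
windows are carried through the recurrence but never stored. The contract
is bit-identical equality with the naive matrix, enforced exhaustively for
all binary pairs with m ≤ 8 and on hundreds of random σ=4 and σ=20 pairs.

Both drivers yield identical stem sets and skip counts by construction;
the 50-instance benchmark asserts it.

## Baseline and post-process

The baseline stemming algorithm builds I = every l-mer (of any sequence)
within 2d of all sequences, then places wildcards for every ordered pair of
I at mutual distance ≤ 2d, including identical pairs (d_x = 0, stems with
exactly d wildcards). That inclusion is what makes the expansion-level
subset relation hold structurally: every stem the drivers emit stays within
d of its generating candidate x, x belongs to I, and the baseline's (x, x)
pair already covers the entire d-ball of x.

Post-processing retains a stem only if every sequence has a window within
distance d of it, with wildcards matching freely; the per-window wildcard
distance equals the minimum over the stem's expansion, so no stem covering
a true motif can be removed (a motif has a ≤ d window everywhere, and the
stem matches the motif at all non-wildcard positions).

## Probabilistic analysis

Under an i.i.d. uniform background the Hamming distance of two random
l-mers is Binomial(l, (σ−1)/σ), so p(t) = P[HD ≤ t] is a binomial tail
(cross-checked against an independent CDF implementation). With t = 2d it
gives the expected per-sequence 2d-neighbor count mp and the crude stem
bound m²·p·2^l·l^d — documented as an order-of-magnitude bound, not a
prediction. With t = d it gives P = 1 − (1−p)^(m−l+1) and the expected
spurious motif count σ^l P^n; the smallest d with that expectation ≥ 1
defines the challenging instance for the benchmark (n = 20, m = 600 unless
stated otherwise). Tails are accumulated via log-gamma terms and
compensated summation so that σ = 20, l = 21 extremes remain accurate.

## Synthetic benchmark generator

The generator reproduces the standard protocol: sequences drawn i.i.d.
uniform; one motif drawn uniformly; per sequence a mismatch count drawn
uniformly from {0, …, d}, that many distinct positions mutated to a
character drawn uniformly from the σ−1 alternatives (guaranteeing true
mismatches), and the mutated copy written over a uniformly chosen window
(plant offset ≤ m − l, so instances never overhang). One private seeded
stream per call; no global random state. Defaults target the standard
benchmark (n = 20, m = 600, protein alphabet).

What the generator does not emulate: compositional bias, repeats,
homology between sequences, multiple motif occurrences per sequence, and
insertions/deletions. Passing tests therefore demonstrate correctness of
the combinatorics and the superset guarantee on the i.i.d. benchmark, not
performance on real proteomes.

## Problem sizes used in the tests

The randomized driver benchmark runs 50 planted instances: 25 protein
(σ=20, l ∈ {7,9,11}, d ∈ 1..3, n ∈ 4..10, m ∈ 40..100) and 25 DNA (σ=4,
l ∈ {7,9}, d ∈ 1..2, n ∈ 4..10, m ∈ 20..50). The DNA subset — where the
brute-force oracle is tractable — backs the superset and subset checks;
σ=4 with d = 3 is excluded because the spurious-motif count explodes on
DNA, which is exactly the regime stem search is not designed for. One
full-scale (9, 2) protein instance at n = 20, m = 600 exercises the
end-to-end pipeline.

## Numerical and design choices

- Ties for the minimal-neighbor sequence break to the lowest sequence
  index; sequences are scanned in input order with early exit on the first
  empty list.
- All driver outputs are lexicographically sorted; stem files are plain
  text, one stem per line, sorted.
- Matrix values are small integers (numpy int64); thresholding at 2d
  happens in the neighbor module, never inside the distance module.
- The brute-force oracle refuses instances whose candidate-enumeration
  estimate (m−l+1)·Σ_{i≤d} C(l,i)(σ−1)^i exceeds a work limit
  (default 5·10⁶) rather than running unbounded.
- Degenerate inputs: m = l yields 1×1 matrices; d = 0 collapses stem
  search to exact common-l-mer matching; d ≥ l admits the all-wildcard
  stem, which post-processing always retains.

## Known limitations

- Candidates come from the first sequence only; if the first sequence is
  atypical (e.g. its planted copy is heavily mutated), the stem set is
  still a guaranteed superset but may be larger than with a better-chosen
  reference.
- The stem count closed form as printed with both binomial upper arguments
  equal to l is implemented as the region-aware product C(d_x, i)·C(l−d_x,
  k), which is what enumeration realises; the l-based version is retained
  only as an upper bound in the tests.
- No bit-parallel distance tricks; the diagonal recurrence is the only
  asymptotic speedup implemented.
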