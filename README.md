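# motifstems

Wildcard motif-stem search for sequence sets over large alphabets.

## The problem

Planted (l, d)-motif search (PMS) asks: given n sequences of length m over an
alphabet Σ (|Σ| = σ), find every l-mer x whose Hamming distance to each
sequence — minimised over that sequence's windows — is at most d. Exact PMS
algorithms enumerate mismatch neighborhoods of size Θ(C(l,d) (σ−1)^d), which
is fine for DNA (σ = 4) but prohibitive for proteins (σ = 20).

*Motif stem search* (MSS) sidesteps the alphabet blow-up: instead of explicit
motifs it returns **stems** — l-length patterns containing wildcard
characters (`*`), each standing for the σ^(#wildcards) l-mers obtained by
filling the wildcards. The output contract is a *superset guarantee*: the
union of the stem expansions contains every (l, d)-motif, and the goal is to
make that superset as small as possible.

This package implements:

- **mss1** — for each candidate l-mer x of the first sequence, compute its
  2d-neighbor offsets in every other sequence on the fly (O(m²nl) time,
  O(m) space); skip x if any sequence has none (no d-neighbor of such an x
  can be a motif, by the triangle inequality); otherwise place wildcards
  between x and each member of I_min, the neighbor list of the sequence
  holding the fewest.
- **mss2** — identical output, but all (m−l+1)² window distances per
  sequence pair come from a diagonal recurrence (consecutive windows share
  an (l−1)-overlap, so each cell follows from its upper-left neighbor in
  O(1)), giving O(m²n) time at O(m²) space.
- **stemming baseline** — the earlier approach: collect every l-mer of every
  sequence within 2d of all sequences into a set I and place wildcards for
  every pair of I; provably a superset (at expansion level) of the mss1/mss2
  output, and much larger in practice.
- **post-process** — optional refinement retaining a stem only if every
  sequence has a window within distance d of it (wildcards match freely).
- **pms_oracle** — a guarded brute-force exact PMS solver used to validate
  the superset guarantee on small instances.
- **analytic machinery** — the binomial tail p(t) = Σ_{i≤t} C(l,i)
  ((σ−1)/σ)^i (1/σ)^(l−i) governing random neighbor counts, the
  per-sequence hit probability P = 1 − (1−p)^(m−l+1), the expected spurious
  motif count σ^l P^n, and the *challenging instance* computation (smallest
  d with that expectation ≥ 1).
- **simulator** — the standard planted benchmark: i.i.d. uniform sequences,
  one motif copy mutated in ≤ d positions embedded per sequence.

## Worked example

Generate a planted protein benchmark (n=20, m=600, l=9, d=2) and search it:

```bash
motifstems simulate --n 20 --m 600 --l 9 --d 2 --alphabet protein \
    --seed 1 --output bench.fasta
# -> # motif: WIRLQTNFR   (also recorded in bench.fasta.meta)

motifstems search --input bench.fasta --l 9 --d 2 --algorithm mss2 \
    --post-process --alphabet protein
```

Output (stems on stdout, counters on stderr):

```
**IRLQTNF
*IRLQTNF*
*WIRLQTN*
W*RLQTNF*
WIRLQTN**
...
# candidates: 592
# skipped: 588
# pairs: 4
# removed_by_post_process: 36
# stems: 18
```

Of the 592 candidate 9-mers in the first sequence, 588 were skipped because
some sequence had no 2d-neighbor; the 4 surviving candidates (the planted
window and its shifted overlaps) produced 54 stems, of which 18 survive
post-processing. Every retained stem matches the planted motif `WIRLQTNFR`
or a shifted window of its planted copy — e.g. `*IRLQTNF*` expands to 400
9-mers including the motif itself.

The closed-form statistics for the same instance class:

```bash
motifstems stats --l 9 --d 2 --sigma 20
# p_at_2d: 3.32e-05                 probability a random window is a 2d-neighbor
# expected_random_motifs: 2.3e-85   spurious (9,2)-motifs expected at n=20, m=600
# challenging_d: 5                  smallest d with >= 1 expected spurious motif
```

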