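"""Closed-form probability analysis for random (l, d) instances.

Under an i.i.d. uniform background over an alphabet of size sigma, the
Hamming distance of two random l-mers is Binomial(l, (sigma-1)/sigma), so

    p(t) = P[HD <= t] = sum_{i=0}^{t} C(l, i) ((sigma-1)/sigma)^i (1/sigma)^(l-i)

This single tail drives everything here: with threshold t = 2d it is the
chance a random window is a 2d-neighbor of a candidate (hence the expected
pair workload m^2 p and the stem-count bound m^2 p 2^l l^d); with t = d it
gives the per-sequence hit probability P = 1 - (1-p)^(m-l+1) and the
expected number of spurious motifs sigma^l P^n, whose crossing of 1
defines the challenging instance (l, d) for a benchmark of n sequences of
length m.
"""

from __future__ import annotations

import math


def p_at_most(l: int, t: int, sigma: int) -> float:
    """P[Hamming distance of two random l-mers <= t], i.i.d. uniform background."""
    if not 0 <= t <= l:
        raise ValueError(f"need 0 <= t <= l, got t={t}, l={l}")
    if sigma < 2:
        raise ValueError("sigma must be at least 2")
    log_mis = math.log(sigma - 1) - math.log(sigma)
    log_match = -math.log(sigma)
    terms = [
        math.exp(math.lgamma(l + 1) - math.lgamma(i + 1) - math.lgamma(l - i + 1)
                 + i * log_mis + (l - i) * log_match)
        for i in range(t + 1)
    ]
    return min(1.0, math.fsum(terms))


def per_sequence_hit_probability(l: int, d: int, sigma: int, m: int) -> float:
    """P = 1 - (1-p)^(m-l+1): chance a random l-mer has a d-neighbor in a sequence."""
    if m < l:
        raise ValueError(f"need m >= l, got m={m}, l={l}")
    p = p_at_most(l, d, sigma)
    return -math.expm1((m - l + 1) * math.log1p(-p)) if p < 1 else 1.0


def expected_random_motifs(l: int, d: int, sigma: int, n: int, m: int) -> float:
    """Expected count of spurious (l, d)-motifs: sigma^l * P^n."""
    P = per_sequence_hit_probability(l, d, sigma, m)
    if P == 0.0:
        return 0.0
    return math.exp(l * math.log(sigma) + n * math.log(P))


def challenging_d(l: int, sigma: int, n: int = 20, m: int = 600) -> int:
    """Smallest d with expected_random_motifs >= 1 (always <= l)."""
    for d in range(l + 1):
        if expected_random_motifs(l, d, sigma, n, m) >= 1.0:
            return d
    return l


def expected_stem_estimate(l: int, d: int, sigma: int, m: int) -> float:
    """Crude upper estimate m^2 * p(2d) * 2^l * l^d on the expected stem count.

    An order-of-magnitude bound, not a prediction: m^2 p(2d) is the
    expected number of candidate pairs and 2^l l^d crudely bounds the
    stems a single pair can yield.
    """
    return m * m * p_at_most(l, min(2 * d, l), sigma) * (2.0**l) * float(l) ** d
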