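"""Shared fixtures: the randomized planted-instance benchmark suite.

The suite mirrors the synthetic benchmark protocol (i.i.d. uniform
background, one mutated motif copy per sequence) at reduced scale so that
the brute-force oracle and the all-pairs baseline stay tractable:
25 protein instances (sigma=20, l in {7,9,11}, d in 1..3, n in 4..10,
m in 40..100) and 25 DNA instances (sigma=4, l in {7,9}, d in 1..2,
n in 4..10, m in 20..50).  Everything is derived from one fixed seed.
"""

from __future__ import annotations

import numpy as np
import pytest

from motifstems import (
    DNA_ALPHABET,
    PROTEIN_ALPHABET,
    PlantedInstance,
    SearchParams,
    generate_planted_instance,
)

SUITE_SEED = 20260901


def make_instance_suite(seed: int = SUITE_SEED) -> list[PlantedInstance]:
    rng = np.random.default_rng(seed)
    suite: list[PlantedInstance] = []
    for _ in range(25):
        l = int(rng.choice([7, 9, 11]))
        d = int(rng.integers(1, 4))
        n = int(rng.integers(4, 11))
        m = int(rng.integers(40, 101))
        suite.append(
            generate_planted_instance(
                n=n, m=m, l=l, d=d, alphabet=PROTEIN_ALPHABET,
                seed=int(rng.integers(0, 2**31)),
            )
        )
    for _ in range(25):
        l = int(rng.choice([7, 9]))
        d = int(rng.integers(1, 3))
        n = int(rng.integers(4, 11))
        m = int(rng.integers(20, 51))
        suite.append(
            generate_planted_instance(
                n=n, m=m, l=l, d=d, alphabet=DNA_ALPHABET,
                seed=int(rng.integers(0, 2**31)),
            )
        )
    return suite


def params_for(instance: PlantedInstance, **kwargs) -> SearchParams:
    return SearchParams(l=instance.l, d=instance.d, **kwargs)


def oracle_feasible(instance: PlantedInstance) -> bool:
    """The subset of the suite the brute-force oracle can handle."""
    return (
        instance.sequence_set.sigma == 4 and instance.l <= 9 and instance.d <= 2
    )


@pytest.fixture(scope="session")
def instance_suite() -> list[PlantedInstance]:
    return make_instance_suite()


@pytest.fixture(scope="session")
def small_dna_instance() -> PlantedInstance:
    return generate_planted_instance(
        n=5, m=50, l=7, d=1, alphabet=DNA_ALPHABET, seed=3
    )
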