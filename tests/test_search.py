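"""Driver-level behavior: hand-checked outputs, flags, oracle guards."""

import pytest

from motifstems import (
    DNA_ALPHABET,
    OracleInfeasibleError,
    SearchParams,
    SequenceSet,
    expand_stem,
    generate_planted_instance,
    mss1,
    mss2,
    pms_oracle,
    post_process,
    stem_distance,
    stemming_baseline,
)
from motifstems.search import StemResult


def windows(s, l):
    return {s[j : j + l] for j in range(len(s) - l + 1)}


class TestMss1:
    def test_identical_sequences_hand_enumeration(self):
        """Two copies of AAAAA, l=3, d=1: every pair has d_x=0 so the only
        budget entry is one matching-region wildcard -> the 3 stems AAA
        with a single wildcard."""
        seqs = SequenceSet(("AAAAA", "AAAAA"), DNA_ALPHABET)
        result = mss1(seqs, SearchParams(l=3, d=1))
        assert set(result.stems) == {"*AA", "A*A", "AA*"}

    def test_d_zero_collapses_to_exact_common_lmers(self):
        inst = generate_planted_instance(4, 30, 5, 0, DNA_ALPHABET, seed=2)
        seqs = inst.sequence_set
        result = mss1(seqs, SearchParams(l=5, d=0))
        common = set.intersection(*(windows(s, 5) for s in seqs.sequences))
        assert set(result.stems) == common
        assert inst.motif in result.stems

    def test_post_processed_stems_cover_a_true_motif(self, small_dna_instance):
        inst = small_dna_instance
        params = SearchParams(l=inst.l, d=inst.d, post_process=True)
        result = mss1(inst.sequence_set, params)
        motifs = pms_oracle(inst.sequence_set, SearchParams(l=inst.l, d=inst.d))
        assert motifs
        for y in motifs:
            assert any(stem_distance(t, y) == 0 for t in result.stems)


class TestMss2Equivalence:
    def test_equals_mss1_on_duplicated_random_sequence(self):
        import numpy as np

        rng = np.random.default_rng(5)
        s = "".join(rng.choice(list(DNA_ALPHABET), 30))
        seqs = SequenceSet((s, s), DNA_ALPHABET)
        params = SearchParams(l=5, d=1)
        assert mss2(seqs, params).stems == mss1(seqs, params).stems

    def test_skip_counters_agree(self, small_dna_instance):
        params = SearchParams(l=7, d=1)
        r1 = mss1(small_dna_instance.sequence_set, params)
        r2 = mss2(small_dna_instance.sequence_set, params)
        assert r1.counters["skipped"] == r2.counters["skipped"]
        assert r1.counters["candidates"] == r2.counters["candidates"]
        assert r1.stems == r2.stems


class TestBaseline:
    def test_superset_of_mss1_on_identical_sequences(self):
        seqs = SequenceSet(("ACGTACGT", "ACGTACGT"), DNA_ALPHABET)
        params = SearchParams(l=4, d=1)
        stems_mss = set(mss1(seqs, params).stems)
        stems_base = set(stemming_baseline(seqs, params).stems)
        exp = lambda stems: set().union(
            *(expand_stem(t, DNA_ALPHABET) for t in stems)
        )
        assert exp(stems_mss) <= exp(stems_base)

    def test_d_zero_identical_to_mss1(self):
        inst = generate_planted_instance(4, 25, 5, 0, DNA_ALPHABET, seed=6)
        params = SearchParams(l=5, d=0)
        assert (
            stemming_baseline(inst.sequence_set, params).stems
            == mss1(inst.sequence_set, params).stems
        )


class TestPostProcess:
    def test_all_wildcard_stem_always_retained(self):
        seqs = SequenceSet(("ACGTA", "TTTTT"), DNA_ALPHABET)
        result = StemResult(stems=("***",))
        kept = post_process(result, seqs, SearchParams(l=3, d=3))
        assert kept.stems == ("***",)

    def test_agrees_with_expansion_oracle(self):
        import numpy as np

        rng = np.random.default_rng(31)
        seqs = SequenceSet(
            tuple("".join(rng.choice(list(DNA_ALPHABET), 15)) for _ in range(3)),
            DNA_ALPHABET,
        )
        params = SearchParams(l=4, d=1)
        patterns = []
        for _ in range(20):
            patterns.append(
                "".join(rng.choice(list(DNA_ALPHABET + "*"), 4))
            )
        kept = post_process(StemResult(stems=tuple(patterns)), seqs, params)
        for pattern in set(patterns):
            expected = all(
                min(
                    min(
                        sum(a != b for a, b in zip(member, s[j : j + 4]))
                        for member in expand_stem(pattern, DNA_ALPHABET)
                    )
                    for j in range(len(s) - 3)
                )
                <= 1
                for s in seqs.sequences
            )
            assert (pattern in kept.stems) == expected

    def test_never_removes_stem_covering_true_motif(self, small_dna_instance):
        inst = small_dna_instance
        params = SearchParams(l=inst.l, d=inst.d)
        result = mss2(inst.sequence_set, params)
        kept = post_process(result, inst.sequence_set, params)
        motifs = pms_oracle(inst.sequence_set, params)
        for y in motifs:
            covering = {t for t in result.stems if stem_distance(t, y) == 0}
            assert covering <= set(kept.stems)


class TestOracle:
    def test_d_zero_equals_common_lmers(self):
        inst = generate_planted_instance(4, 30, 5, 0, DNA_ALPHABET, seed=2)
        seqs = inst.sequence_set
        motifs = set(pms_oracle(seqs, SearchParams(l=5, d=0)))
        assert motifs == set.intersection(*(windows(s, 5) for s in seqs.sequences))

    def test_contains_planted_motif(self):
        inst = generate_planted_instance(5, 50, 7, 1, DNA_ALPHABET, seed=12)
        motifs = pms_oracle(inst.sequence_set, SearchParams(l=7, d=1))
        assert inst.motif in motifs

    def test_monotone_in_d(self, small_dna_instance):
        seqs = small_dna_instance.sequence_set
        previous: set[str] = set()
        for d in range(0, 3):
            current = set(pms_oracle(seqs, SearchParams(l=7, d=d)))
            assert previous <= current
            previous = current

    def test_infeasible_scale_guarded(self):
        inst = generate_planted_instance(
            3, 60, 15, 7, "ACDEFGHIKLMNPQRSTVWY", seed=1
        )
        with pytest.raises(OracleInfeasibleError):
            pms_oracle(inst.sequence_set, SearchParams(l=15, d=7))


class TestParams:
    def test_invalid_parameters_rejected(self):
        seqs = SequenceSet(("ACGT", "ACGT"), DNA_ALPHABET)
        with pytest.raises(ValueError):
            mss1(seqs, SearchParams(l=5, d=1))
        with pytest.raises(ValueError):
            mss2(seqs, SearchParams(l=3, d=4))

    def test_post_process_flag_filters_output(self, small_dna_instance):
        inst = small_dna_instance
        raw = mss2(inst.sequence_set, SearchParams(l=inst.l, d=inst.d))
        refined = mss2(
            inst.sequence_set,
            SearchParams(l=inst.l, d=inst.d, post_process=True),
        )
        assert set(refined.stems) <= set(raw.stems)

    def test_result_ordering_is_lexicographic(self, small_dna_instance):
        result = mss2(
            small_dna_instance.sequence_set,
            SearchParams(l=small_dna_instance.l, d=small_dna_instance.d),
        )
        assert list(result.stems) == sorted(result.stems)
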