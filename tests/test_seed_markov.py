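"""Transition matrices, first-order Markov k-mer probabilities, seed scanning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connectedrules.io import SequenceRecord
from connectedrules.seed_markov import (
    BASE_ORDER,
    TransitionMatrix,
    build_transition_matrix,
    mm_probability,
    reverse_complement,
    scan_seed,
)

# Printed dinucleotide counts and base composition of a 675-nt 5' UTR,
# used as an external count table (row/col order A, G, U, C).
UTR_COUNTS = np.array(
    [
        [33, 50, 32, 36],
        [60, 60, 20, 42],
        [22, 33, 62, 44],
        [36, 38, 47, 60],
    ]
)
UTR_COMPOSITION = np.array([151, 182, 161, 181])
UTR_LENGTH = 675


def _random_seq(rng, length):
    return SequenceRecord(
        "rnd", "5UTR", "".join(rng.choice(list("ACGU"), length))
    )


class TestTransitionMatrix:
    def test_homopolymer(self):
        tm = build_transition_matrix(SequenceRecord("x", "3UTR", "AAAA"))
        assert tm.counts[0, 0] == 3
        assert tm.probs[0, 0] == 1.0
        assert "G" in tm.zero_rows

    def test_each_adjacent_pair_counted_once(self):
        tm = build_transition_matrix(SequenceRecord("x", "3UTR", "ACGU"))
        idx = {b: i for i, b in enumerate(BASE_ORDER)}
        assert tm.counts[idx["A"], idx["C"]] == 1
        assert tm.counts[idx["C"], idx["G"]] == 1
        assert tm.counts[idx["G"], idx["U"]] == 1
        assert tm.counts.sum() == 3

    def test_row_sums_are_composition_minus_terminal(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 675)
        tm = build_transition_matrix(seq)
        terminal = seq.sequence[-1]
        for i, b in enumerate(BASE_ORDER):
            expected = tm.composition[i] - (1 if b == terminal else 0)
            assert tm.counts[i].sum() == expected
        assert tm.composition.sum() == 675
        for i in range(4):
            if tm.counts[i].sum():
                assert tm.probs[i].sum() == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_on_copy(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 200)
        copy = SequenceRecord(seq.id, seq.region_tag, str(seq.sequence))
        a, b = build_transition_matrix(seq), build_transition_matrix(copy)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.probs, b.probs)

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            build_transition_matrix(SequenceRecord("x", "3UTR", "A"))


class TestMmProbability:
    def test_uniform_chain_closed_form(self):
        tm = TransitionMatrix.from_counts(
            np.full((4, 4), 25), np.full(4, 100), 400
        )
        assert mm_probability("AAAAAAA", tm) == pytest.approx(0.25**7)

    def test_printed_count_table_heptamer(self):
        tm = TransitionMatrix.from_counts(UTR_COUNTS, UTR_COMPOSITION, UTR_LENGTH)
        expected = (151 / 675) * (33 / 151) ** 6
        assert mm_probability("AAAAAAA", tm) == pytest.approx(expected)
        assert expected == pytest.approx(2.44e-5, rel=5e-3)

    @pytest.mark.parametrize("k", [1, 2, 3, 7])
    def test_total_probability_sums_to_one(self, k):
        tm = TransitionMatrix.from_counts(UTR_COUNTS, UTR_COMPOSITION, UTR_LENGTH)
        total = sum(
            mm_probability("".join(kmer), tm)
            for kmer in itertools.product(BASE_ORDER, repeat=k)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_transition_gives_zero(self):
        tm = build_transition_matrix(SequenceRecord("x", "3UTR", "AAAA"))
        assert mm_probability("AG", tm) == 0.0


class TestScanSeed:
    def test_perfect_site_coordinates(self):
        # reverse complement of A^7 is U^7 at positions 3..9 (1-based)
        seq = SequenceRecord("g", "3UTR", "GGUUUUUUUGG")
        matches = scan_seed("AAAAAAA", seq, max_mismatch=0)
        assert len(matches) == 1
        m = matches[0]
        assert (m.start, m.end, m.mismatches) == (3, 9, 0)
        assert m.site_sequence == "UUUUUUU"

    def test_mismatch_budget(self):
        seq = SequenceRecord("g", "3UTR", "GGUUUAUUUGG")  # one U->A mismatch
        assert scan_seed("AAAAAAA", seq, max_mismatch=0) == []
        matches = scan_seed("AAAAAAA", seq, max_mismatch=1)
        assert matches and all(m.mismatches == 1 for m in matches)

    def test_matches_equal_window_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        seq_str = "".join(rng.choice(list("ACGU"), 60))
        seed = "GUCAAGU"
        site = reverse_complement(seed)
        seq_str = seq_str[:20] + site + seq_str[27:]  # plant a perfect site
        seq = SequenceRecord("g", "5UTR", seq_str)
        k = len(seed)
        for mm_budget in (0, 1, 2):
            expected = [
                (i + 1, sum(a != b for a, b in zip(seq_str[i : i + k], site)))
                for i in range(len(seq_str) - k + 1)
                if sum(a != b for a, b in zip(seq_str[i : i + k], site)) <= mm_budget
            ]
            got = [(m.start, m.mismatches) for m in scan_seed(seed, seq, max_mismatch=mm_budget)]
            assert got == expected

    def test_wobble_flag_admits_gu_pairs(self):
        # seed G pairs C canonically; window U is a G-U wobble
        seq = SequenceRecord("g", "3UTR", "AAUUUUUUUAA")
        seed = "AAAAAAG"  # revcomp = CUUUUUU; window UUUUUUU has U where C expected
        assert scan_seed(seed, seq, max_mismatch=0) == []
        assert scan_seed(seed, seq, max_mismatch=0, allow_wobble=True)

    def test_site_sequence_slices_coordinates(self):
        rng = np.random.default_rng(4)
        seq = _random_seq(rng, 120)
        for m in scan_seed("ACGUACG", seq, max_mismatch=2):
            assert m.site_sequence == seq.sequence[m.start - 1 : m.end]
            assert m.end - m.start + 1 == 7
            assert 0 < m.p_exact <= 1
            assert m.p_window >= m.p_exact

    def test_bad_seed_rejected(self):
        seq = SequenceRecord("g", "3UTR", "ACGUACGU")
        with pytest.raises(ValueError):
            scan_seed("ACGXACG", seq)
        with pytest.raises(ValueError):
            scan_seed("ACGU", seq)  # too short


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed_int=st.integers(0, 2**16), budget=st.integers(1, 3))
def test_mismatch_superset_property(seed_int, budget):
    """Raising the mismatch budget never loses matches."""
    rng = np.random.default_rng(seed_int)
    seq = _random_seq(rng, 80)
    seed = "".join(rng.choice(list("ACGU"), 7))
    lo = {(m.start, m.end) for m in scan_seed(seed, seq, max_mismatch=budget - 1)}
    hi = {(m.start, m.end) for m in scan_seed(seed, seq, max_mismatch=budget)}
    assert lo <= hi


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed_int=st.integers(0, 2**16), k=st.integers(1, 4))
def test_normalization_on_random_sequences(seed_int, k):
    """Σ over all k-mers of the Markov probability is 1 for estimated chains."""
    rng = np.random.default_rng(seed_int)
    seq = _random_seq(rng, 150)
    tm = build_transition_matrix(seq)
    total = sum(
        mm_probability("".join(km), tm) for km in itertools.product(BASE_ORDER, repeat=k)
    )
    assert total == pytest.approx(1.0, abs=1e-9)
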