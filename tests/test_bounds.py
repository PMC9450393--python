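import random
from fractions import Fraction

import pytest

from minimlcs import (
    ALL_STRATEGIES,
    BoundsConfig,
    MatchPoint,
    SequenceSet,
    beam_lower_bound,
    brute_force_distance,
    brute_force_mlcs,
    build_successor_table,
    diversity,
    estimate_lower_bound,
    origin,
    phi,
    precompute_strategy2,
    precompute_strategy3,
    prepare_bounds,
    select_diverse_subset,
    upper_strategy2,
    upper_strategy3,
    upper_theorem1,
    combined_upper,
)
from conftest import all_match_points, random_instances


@pytest.mark.parametrize(
    "coords, expected",
    [((0, 0, 0), 0), ((1, 3, 2), 2), ((5, 6, 6), 1)],
)
def test_phi(coords, expected):
    assert phi(MatchPoint(coords)) == expected


class TestLowerBound:
    def test_worked_example_beam_width_four(self, example, example_table):
        assert beam_lower_bound(example, example_table, 4, random.Random(0)) == 5

    def test_estimator_on_worked_example(self, example, example_table):
        assert estimate_lower_bound(example, example_table, BoundsConfig(t0=4)) == 5

    def test_identical_copies_reach_full_length(self):
        # a single narrow beam may tie-break onto a short chain (all four
        # successors of O have phi = 0), but the restarting estimator widens
        # the beam and always recovers the diagonal chain of length |s|
        seqs = SequenceSet.from_strings(["ACGT"] * 3)
        st = build_successor_table(seqs)
        for t in (4, 5):
            assert beam_lower_bound(seqs, st, t, random.Random(0)) == 4
        for t0 in (1, 2, 5):
            assert estimate_lower_bound(seqs, st, BoundsConfig(t0=t0)) == 4

    def test_disjoint_alphabets_give_zero(self):
        seqs = SequenceSet.from_strings(["AAAA", "CCCC", "GGGG"])
        st = build_successor_table(seqs)
        assert estimate_lower_bound(seqs, st, BoundsConfig()) == 0

    def test_estimator_is_deterministic_per_seed(self, example, example_table):
        a = estimate_lower_bound(example, example_table, BoundsConfig(seed=7))
        b = estimate_lower_bound(example, example_table, BoundsConfig(seed=7))
        assert a == b

    def test_never_exceeds_true_length(self):
        for i, seqs in random_instances(40):
            st = build_successor_table(seqs)
            lower = estimate_lower_bound(seqs, st, BoundsConfig(seed=i))
            assert 0 <= lower <= brute_force_mlcs(seqs).length

    def test_exhaustive_beam_reaches_true_length(self):
        for i, seqs in random_instances(20, dims=(3,), n_range=(5, 10)):
            st = build_successor_table(seqs)
            big_t = len(all_match_points(seqs)) + 1
            assert (
                beam_lower_bound(seqs, st, big_t, random.Random(i))
                == brute_force_mlcs(seqs).length
            )


class TestTheorem1:
    @pytest.mark.parametrize(
        "coords, expected", [((6, 4, 4), 2), ((4, 2, 5), 3), ((8, 8, 8), 0)]
    )
    def test_worked_example_values(self, example, coords, expected):
        assert upper_theorem1(MatchPoint(coords), example) == expected

    def test_unequal_lengths_use_shortest_remaining(self):
        seqs = SequenceSet.from_strings(["ACGTACGT", "ACG"])
        assert upper_theorem1(MatchPoint((1, 1), "A"), seqs) == 2


class TestStrategy2:
    def test_suffix_counts_of_example(self, example):
        counts = precompute_strategy2(example, (0, 1, 2))
        order = sorted(example.alphabet)  # A C G T
        # suffix after position 4 of s1 is TCGT
        assert [int(counts[0][order.index(c), 4]) for c in "ACGT"] == [0, 1, 1, 2]
        # empty suffix counts nothing; whole-sequence column counts everything
        assert counts[0][:, 8].sum() == 0
        assert counts[0][:, 0].sum() == 8

    def test_bound_at_G455_is_two(self, example, example_table):
        state = prepare_bounds(example, example_table, estimate_lower=False)
        assert upper_strategy2(MatchPoint((4, 5, 5), "G"), state) == 2

    def test_bound_at_origin_and_ends(self, example, example_table):
        state = prepare_bounds(example, example_table, estimate_lower=False)
        assert upper_strategy2(origin(3), state) == 6
        assert upper_strategy2(MatchPoint((8, 8, 8)), state) == 0


class TestStrategy3:
    def test_pairwise_suffix_lcs_entries(self, example):
        mats = precompute_strategy3(example, (0, 1, 2))
        m12 = mats[0]
        assert m12[4, 2] == 3  # LCS(TCGT, ACGTCC)
        assert m12[8, 8] == 0
        ident = precompute_strategy3(
            SequenceSet.from_strings(["ACGT", "ACGT"]), (0, 1)
        )[0]
        assert all(ident[j, j] == 4 - j for j in range(5))

    def test_bound_at_G421_is_three(self, example, example_table):
        state = prepare_bounds(example, example_table, estimate_lower=False)
        assert upper_strategy3(MatchPoint((4, 2, 1), "G"), state) == 3

    def test_bound_at_origin_and_ends(self, example, example_table):
        state = prepare_bounds(example, example_table, estimate_lower=False)
        assert upper_strategy3(origin(3), state) == 5
        assert upper_strategy3(MatchPoint((8, 8, 8)), state) == 0


class TestDiversity:
    def test_worked_example_values(self, example):
        s1, s2, s3 = example.sequences
        # per the weighted count-difference formula: s2 differs more than s3
        assert diversity(s1, s3) == Fraction(1, 2)
        assert diversity(s1, s2) > diversity(s1, s3)

    def test_self_diversity_is_zero(self, example):
        for s in example.sequences:
            assert diversity(s, s) == 0

    def test_always_non_negative(self):
        for _, seqs in random_instances(20):
            for si in seqs:
                for sj in seqs:
                    assert diversity(si, sj) >= 0


class TestSelectDiverseSubset:
    def test_worked_example_pairs_anchor_with_s2(self, example):
        assert select_diverse_subset(example, 2) == (0, 1)

    def test_delta_extremes(self, example):
        assert select_diverse_subset(example, 1) == (0,)
        assert set(select_diverse_subset(example, 3)) == {0, 1, 2}

    def test_order_is_descending_diversity(self, example):
        sel = select_diverse_subset(example, 3)
        s1 = example.sequences[0]
        divs = [diversity(s1, example.sequences[j]) for j in sel[1:]]
        assert divs == sorted(divs, reverse=True)


class TestCombinedUpper:
    def test_minimum_of_enabled_bounds(self, example, example_table):
        cfg = BoundsConfig()
        state = prepare_bounds(example, example_table, cfg, estimate_lower=False)
        p = MatchPoint((4, 2, 1), "G")
        expected = min(
            upper_theorem1(p, example),
            upper_strategy2(p, state),
            upper_strategy3(p, state),
        )
        assert combined_upper(p, state, cfg) == expected == 3

    def test_theorem1_only(self, example, example_table):
        cfg = BoundsConfig(strategies=frozenset({"theorem1"}))
        state = prepare_bounds(example, example_table, cfg, estimate_lower=False)
        p = MatchPoint((4, 2, 1), "G")
        assert combined_upper(p, state, cfg) == upper_theorem1(p, example) == 4

    def test_no_strategy_falls_back_to_remaining_length(self, example, example_table):
        cfg = BoundsConfig(strategies=frozenset())
        state = prepare_bounds(example, example_table, cfg, estimate_lower=False)
        p = MatchPoint((6, 4, 4), "C")
        assert combined_upper(p, state, cfg) == 2


class TestAdmissibility:
    """Every bound must dominate the true remaining distance everywhere."""

    def test_bounds_dominate_brute_force_distance(self):
        for i, seqs in random_instances(100):
            st = build_successor_table(seqs)
            state = prepare_bounds(seqs, st, estimate_lower=False)
            for p in all_match_points(seqs):
                dist = brute_force_distance(p, seqs)
                assert upper_theorem1(p, seqs) >= dist
                assert upper_strategy2(p, state) >= dist
                assert upper_strategy3(p, state) >= dist

    def test_subset_bounds_are_no_tighter_than_full(self):
        for i, seqs in random_instances(30, dims=(4, 5)):
            st = build_successor_table(seqs)
            full = prepare_bounds(
                seqs, st, BoundsConfig(delta=seqs.d), estimate_lower=False
            )
            sub = prepare_bounds(
                seqs, st, BoundsConfig(delta=2), estimate_lower=False
            )
            for p in all_match_points(seqs)[::5]:
                assert upper_strategy2(p, sub) >= upper_strategy2(p, full)
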