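"""Fraction of genome altered, its binning, and the rank-sum burden
comparison (checked against exhaustive enumeration and scipy)."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from genoinstab._stats import rank_sum_test
from genoinstab.io import GenomeDef, Segment, SegmentProfile
from genoinstab.scna import (
    bin_fga,
    compare_burden,
    fraction_genome_altered,
)


def _profile(segs):
    return SegmentProfile("S1", [Segment("S1", *s) for s in segs]).validate()


class TestFractionGenomeAltered:
    def test_worked_example(self, toy_genome):
        # 60 + 40 Mb genome; 5 Mb + 15 Mb altered -> 0.20
        profile = _profile([
            ("chr1", 0, 5_000_000, -1.0),
            ("chr1", 5_000_000, 60_000_000, 0.0),
            ("chr2", 0, 15_000_000, 0.8),
            ("chr2", 15_000_000, 40_000_000, 0.05),
        ])
        assert fraction_genome_altered(profile, toy_genome) == pytest.approx(0.20)

    def test_no_segment_beyond_threshold(self, toy_genome):
        profile = _profile([("chr1", 0, 60_000_000, 0.1)])
        assert fraction_genome_altered(profile, toy_genome) == 0.0

    def test_whole_genome_deleted(self, toy_genome):
        profile = _profile([
            ("chr1", 0, 60_000_000, -1.0), ("chr2", 0, 40_000_000, -1.0)
        ])
        assert fraction_genome_altered(profile, toy_genome) == 1.0

    def test_empty_profile_warns_and_returns_zero(self, toy_genome):
        with pytest.warns(UserWarning):
            assert fraction_genome_altered(SegmentProfile("S1"), toy_genome) == 0.0

    def test_threshold_boundary_inclusive(self, toy_genome):
        profile = _profile([("chr1", 0, 60_000_000, 0.2)])
        assert fraction_genome_altered(profile, toy_genome) == pytest.approx(0.6)

    @given(st.integers(min_value=1, max_value=59_999_999))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_segment_splitting(self, split):
        toy = GenomeDef((("chr1", 60_000_000), ("chr2", 40_000_000)))
        whole = _profile([("chr1", 0, 60_000_000, -0.9)])
        split_profile = _profile([
            ("chr1", 0, split, -0.9), ("chr1", split, 60_000_000, -0.9)
        ])
        assert fraction_genome_altered(whole, toy) == pytest.approx(
            fraction_genome_altered(split_profile, toy)
        )


class TestBinFga:
    def test_first_two_bins(self):
        counts = bin_fga([0.005, 0.02])
        assert counts.iloc[0] == 1 and counts.iloc[1] == 1

    def test_boundary_value_falls_in_bin_it_opens(self):
        counts = bin_fga([0.5])
        assert counts[">=0.5"] == 1
        assert bin_fga([0.01])["[0.01,0.05)"] == 1

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=0, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_counts_conserved(self, values):
        assert bin_fga(values).sum() == len(values)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_fga([1.2])


def enumeration_oracle(x, y):
    """Independent brute-force: enumerate every assignment of the pooled
    values to group positions and tally rank-sum tail probabilities."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[: len(x)].sum()
    total = comb(len(pooled), len(x))
    ge = sum(1 for idx in combinations(range(len(pooled)), len(x))
             if ranks[list(idx)].sum() >= w_obs - 1e-9)
    le = sum(1 for idx in combinations(range(len(pooled)), len(x))
             if ranks[list(idx)].sum() <= w_obs + 1e-9)
    return ge / total, le / total


class TestRankSum:
    def test_textbook_extreme_split(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.exact
        assert res.p_one == pytest.approx(1 / 20)
        assert res.direction == -1

    def test_identical_multisets_two_sided_p_is_one(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert res.p_two == 1.0
        assert res.direction == 0

    def test_label_swap_symmetry(self, rng):
        x, y = rng.normal(size=7), rng.normal(size=5)
        a, b = rank_sum_test(x, y), rank_sum_test(y, x)
        assert a.p_two == pytest.approx(b.p_two)
        assert a.p_greater == pytest.approx(b.p_less)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 9, size=2)
        x = rng.integers(0, 5, size=nx).astype(float)  # heavy ties
        y = rng.integers(0, 5, size=ny).astype(float)
        res = rank_sum_test(x, y)
        ge, le = enumeration_oracle(x, y)
        assert res.exact
        assert res.p_greater == pytest.approx(ge, abs=1e-12)
        assert res.p_less == pytest.approx(le, abs=1e-12)

    def test_asymptotic_path_matches_scipy(self, rng):
        x, y = rng.normal(size=30), rng.normal(0.5, 1, size=25)
        res = rank_sum_test(x, y)
        expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
        assert not res.exact
        assert res.p_two == pytest.approx(expected, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestCompareBurden:
    def test_histograms_and_p(self):
        values = pd.Series(
            [0.005, 0.02, 0.03, 0.3, 0.45, 0.6],
            index=[f"S{i}" for i in range(6)],
        )
        groups = pd.Series(["wt", "wt", "wt", "mut", "mut", "mut"],
                           index=values.index)
        cmp_result = compare_burden(values, groups)
        assert cmp_result.p_one == pytest.approx(1 / 20)
        assert cmp_result.histograms.sum().tolist() == [3, 3]
        # swapping labels leaves the two-sided p unchanged
        swapped = compare_burden(values, groups.map({"wt": "mut", "mut": "wt"}))
        assert swapped.p_two == pytest.approx(cmp_result.p_two)

    def test_needs_two_groups(self):
        values = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            compare_burden(values, pd.Series(["g", "g"], index=["a", "b"]))
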