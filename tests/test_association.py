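"""Lesion matrix construction, burden association, BH control, and the
one-tail Fisher exclusivity test (checked against hypergeometric sums)."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genoinstab.association import (
    associate_lesion_with_burden,
    build_lesion_matrix,
    mutual_exclusivity,
    rank_associations,
    AssociationResult,
)
from genoinstab.io import MutationObservation, Region, Segment, SegmentProfile
from genoinstab._stats import bh_qvalues


def _mut(sample, gene):
    return MutationObservation(sample, "chr1", 100, gene, 60, 40, 0.8, 2)


def _del_profile(sample, log2):
    return SegmentProfile(sample, [Segment(sample, "chr5", 0, 10_000, log2)])


class TestBuildLesionMatrix:
    def test_point_and_deletion_calls(self):
        samples = [f"S{i}" for i in range(6)]
        muts = [_mut(s, "SPOP") for s in samples[:3]]
        profiles = [_del_profile("S3", -0.8), _del_profile("S4", -0.3),
                    _del_profile("S5", -0.1)]
        regions = [Region("del_5q", "chr5", 0, 20_000)]
        matrix = build_lesion_matrix(muts, profiles, regions, samples,
                                     min_recurrence=2)
        assert matrix.presence["SPOP"].tolist() == [1, 1, 1, 0, 0, 0]
        # -0.8 and -0.3 pass log2 <= -0.2; -0.1 does not
        assert matrix.presence["del_5q"].tolist() == [0, 0, 0, 1, 1, 0]
        assert matrix.kinds["SPOP"] == "point_mutation"
        assert matrix.kinds["del_5q"] == "deletion"

    def test_min_recurrence_filters(self):
        samples = [f"S{i}" for i in range(6)]
        muts = [_mut("S0", "RARE"), _mut("S1", "RARE")]
        matrix = build_lesion_matrix(muts, [], [], samples, min_recurrence=3)
        assert "RARE" not in matrix.lesions

    def test_overlapping_regions_rejected(self):
        regions = [Region("a", "chr5", 0, 100), Region("b", "chr5", 50, 200)]
        with pytest.raises(Exception, match="overlap"):
            build_lesion_matrix([], [], regions, ["S0"])


class TestAssociation:
    def test_enumerated_one_sided_p(self):
        burden = pd.Series([200, 210, 220, 20, 25, 30, 35],
                           index=[f"S{i}" for i in range(7)])
        presence = pd.Series([1, 1, 1, 0, 0, 0, 0], index=burden.index)
        res = associate_lesion_with_burden(presence, burden, lesion="L")
        # carriers occupy the 3 extreme ranks: 1 of C(7,3)=35 assignments
        assert res.p_value == pytest.approx(2 / 35)
        assert res.direction == 1
        assert res.minus_log10_p == pytest.approx(-np.log10(2 / 35))

    def test_sample_order_irrelevant(self, rng):
        burden = pd.Series(rng.poisson(30, 40), index=[f"S{i}" for i in range(40)])
        presence = pd.Series(rng.integers(0, 2, 40), index=burden.index)
        res1 = associate_lesion_with_burden(presence, burden)
        perm = rng.permutation(40)
        res2 = associate_lesion_with_burden(presence.iloc[perm], burden.iloc[perm])
        assert res1.p_value == pytest.approx(res2.p_value)

    def test_all_or_no_carriers_rejected(self):
        burden = pd.Series([1, 2, 3], index=list("abc"))
        with pytest.raises(ValueError):
            associate_lesion_with_burden(pd.Series([1, 1, 1], index=list("abc")),
                                         burden)

    def test_null_calibration(self):
        """Burden independent of presence: the engine's fixed-direction tail
        is uniform, and the reported two-sided p rejects at most at nominal
        rate (it is mildly conservative from the continuity correction)."""
        from genoinstab._stats import rank_sum_test

        rng = np.random.default_rng(5)
        tails, pvals = [], []
        for _ in range(2000):
            burden = pd.Series(rng.normal(size=30))
            presence = pd.Series(np.r_[np.ones(10, int), np.zeros(20, int)])
            res = associate_lesion_with_burden(presence, burden)
            pvals.append(res.p_value)
            carriers = burden[presence == 1].to_numpy()
            rest = burden[presence == 0].to_numpy()
            tails.append(rank_sum_test(carriers, rest).p_greater)
        assert stats.kstest(tails, "uniform").pvalue > 0.01
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.06


class TestRankAssociations:
    @staticmethod
    def _results(ps):
        return [
            AssociationResult(f"L{i}", "n_intra", 5, 5, 1, p, -np.log10(p))
            for i, p in enumerate(ps)
        ]

    def test_bh_step_up_example(self):
        ranked = rank_associations(self._results([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(ranked["q_value"], 0.04)

    def test_single_lesion_q_equals_p(self):
        ranked = rank_associations(self._results([0.0123]))
        assert ranked["q_value"].iloc[0] == pytest.approx(0.0123)

    def test_adding_null_lesion_never_lowers_q(self):
        base = rank_associations(self._results([0.01, 0.2, 0.5]))
        extended = rank_associations(self._results([0.01, 0.2, 0.5, 1.0]))
        merged = base.merge(extended, on="lesion", suffixes=("_b", "_e"))
        assert (merged["q_value_e"] >= merged["q_value_b"] - 1e-12).all()


def hypergeom_tail_oracle(both, a_only, b_only, neither):
    """Brute-force P(overlap <= both) by summing hypergeometric terms."""
    n = both + a_only + b_only + neither
    n_a, n_b = both + a_only, both + b_only
    total = comb(n, n_b)
    acc = 0
    for k in range(0, both + 1):
        if k <= n_a and n_b - k <= n - n_a:
            acc += comb(n_a, k) * comb(n - n_a, n_b - k)
    return acc / total


class TestMutualExclusivity:
    @staticmethod
    def _cols(a, b):
        idx = [f"S{i}" for i in range(len(a))]
        return pd.Series(a, index=idx), pd.Series(b, index=idx)

    def test_disjoint_three_vs_three_of_six(self):
        a, b = self._cols([1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1])
        res = mutual_exclusivity(a, b)
        assert res.p_value == pytest.approx(1 / comb(6, 3))  # 0.05

    def test_identical_columns_not_exclusive(self):
        a, b = self._cols([1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 0])
        assert mutual_exclusivity(a, b).p_value == pytest.approx(1.0)

    def test_symmetric_in_a_and_b(self, rng):
        av = rng.integers(0, 2, 25)
        bv = rng.integers(0, 2, 25)
        a, b = self._cols(av, bv)
        r1, r2 = mutual_exclusivity(a, b), mutual_exclusivity(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_zero_margin_degenerate(self):
        a, b = self._cols([0, 0, 0, 0], [1, 1, 0, 0])
        res = mutual_exclusivity(a, b)
        assert res.degenerate and res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 31))
        av = (rng.random(n) < 0.4).astype(int)
        bv = (rng.random(n) < 0.4).astype(int)
        a, b = self._cols(av, bv)
        res = mutual_exclusivity(a, b)
        if res.degenerate:
            return
        oracle = hypergeom_tail_oracle(res.n_both, res.n_a_only, res.n_b_only,
                                       res.n_neither)
        assert res.p_value == pytest.approx(oracle, abs=1e-12)
        table = [[res.n_both, res.n_a_only], [res.n_b_only, res.n_neither]]
        scipy_p = stats.fisher_exact(table, alternative="less")[1]
        assert res.p_value == pytest.approx(scipy_p, abs=1e-9)


def test_bh_qvalues_empty():
    assert bh_qvalues([]).size == 0
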