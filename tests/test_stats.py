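import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from prscohort.scoring import OrientedGenotypes
from prscohort.stats import (
    bh_adjust,
    carrier_cooccurrence,
    cooccurrence_difference,
    fisher_allele_test,
    fisher_exact_pvalue,
    fisher_pvalue_grid,
    fit_prs_logistic,
    sample_skewness,
    skewness_normality_test,
)


class TestLogisticOddsRatio:
    def test_binary_covariate_recovers_2x2_odds_ratio(self):
        # case carriers 8:2, control carriers 5:5 -> OR = (8*5)/(2*5) = 4
        x = np.r_[np.ones(8), np.zeros(2), np.ones(5), np.zeros(5)]
        y = np.r_[np.ones(10), np.zeros(10)].astype(bool)
        r = fit_prs_logistic(x, y)
        assert r.or_ == pytest.approx(4.0, rel=1e-5)
        assert r.ci_low <= r.or_ <= r.ci_high

    def test_label_swap_inverts_the_odds_ratio(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=120)
        y = rng.random(120) < 1 / (1 + np.exp(-x))
        r1 = fit_prs_logistic(x, y)
        r2 = fit_prs_logistic(x, ~y)
        assert r2.beta == pytest.approx(-r1.beta, abs=1e-6)
        assert r2.or_ == pytest.approx(1 / r1.or_, rel=1e-5)

    def test_null_scores_rarely_reject(self):
        rng = np.random.default_rng(42)
        ok = 0
        for _ in range(100):
            x = rng.normal(size=400)
            y = np.r_[np.ones(200), np.zeros(200)].astype(bool)
            r = fit_prs_logistic(x, y)
            if 0.7 <= r.or_ <= 1.4 and r.p_wald > 0.05:
                ok += 1
        assert ok >= 90

    def test_complete_separation_raises(self):
        x = np.r_[np.linspace(2, 3, 20), np.linspace(-3, -2, 20)]
        y = np.r_[np.ones(20), np.zeros(20)].astype(bool)
        with pytest.raises(ValueError):
            fit_prs_logistic(x, y)

    def test_zero_variance_score_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_prs_logistic(np.ones(20), np.r_[np.ones(10), np.zeros(10)].astype(bool))


class TestSampleSkewness:
    def test_symmetric_sample_has_zero_skew(self):
        assert sample_skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-15)

    def test_hand_example_mixed_denominators(self):
        # numerator (1/4) * sum d^3 = 0.09375; denominator (1/3 * 0.75)^1.5 = 0.125
        assert sample_skewness([0.0, 0.0, 0.0, 1.0]) == pytest.approx(0.75)

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_odd_symmetry(self, xs):
        x = np.asarray(xs)
        if np.ptp(x) < 1e-6:  # avoid variance underflow, not just exact ties
            return
        assert sample_skewness(-x) == pytest.approx(-sample_skewness(x), abs=1e-8)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            sample_skewness([2.0, 2.0, 2.0])


class TestSkewnessNormalityTest:
    def test_p_respects_add_one_lower_bound(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(size=51) * -1  # strongly left-skewed
        r = skewness_normality_test(x, n_sim=1000, seed=1)
        assert r.p_value >= 1 / 1001
        assert r.b1 < 0
        assert r.p_value < 0.05

    def test_seeded_reproducibility(self):
        x = np.random.default_rng(3).normal(size=51)
        r1 = skewness_normality_test(x, n_sim=2000, seed=7)
        r2 = skewness_normality_test(x, n_sim=2000, seed=7)
        assert r1.p_value == r2.p_value

    def test_normal_sample_usually_accepted(self):
        rng = np.random.default_rng(11)
        rejections = sum(
            skewness_normality_test(
                rng.standard_normal(51), n_sim=1000, seed=int(rng.integers(2**31))
            ).p_value
            < 0.05
            for _ in range(100)
        )
        assert rejections <= 12

    def test_minimum_sizes_enforced(self):
        with pytest.raises(ValueError):
            skewness_normality_test(np.arange(5.0), n_sim=2000)
        with pytest.raises(ValueError):
            skewness_normality_test(np.arange(20.0), n_sim=10)


class TestFisherAlleleTest:
    def test_identical_allele_counts_give_p_one(self):
        assert fisher_exact_pvalue(3, 3, 7, 7) == 1.0

    def test_hand_enumerated_table(self):
        # [[3,7],[7,3]]: 2 * 16526 / 184756
        assert fisher_exact_pvalue(3, 7, 7, 3) == pytest.approx(
            2 * 16526 / 184756, abs=1e-12
        )

    def test_allele_row_swap_invariance(self):
        assert fisher_exact_pvalue(3, 7, 7, 3) == fisher_exact_pvalue(7, 3, 3, 7)

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 40, size=4)
            if a + c == 0 or b + d == 0:
                continue
            ours = fisher_exact_pvalue(a, b, c, d)
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_grid_matches_scalar(self):
        P = fisher_pvalue_grid(9, 11)
        for a in range(10):
            for b in range(12):
                assert P[a, b] == pytest.approx(
                    fisher_exact_pvalue(a, b, 9 - a, 11 - b), abs=1e-14
                )

    def test_counts_from_dosages_exclude_missing(self):
        case = np.array([2.0, 1.0, np.nan])
        ctrl = np.array([0.0, 0.0, 1.0, 1.0])
        r = fisher_allele_test(case, ctrl, ("1", 5, "A", "G"))
        assert (r.case_effect, r.case_total) == (3, 4)
        assert (r.control_effect, r.control_total) == (2, 8)

    def test_zero_alleles_in_a_cohort_raises(self):
        with pytest.raises(ValueError):
            fisher_allele_test(np.array([np.nan]), np.array([1.0]))


class TestBHAdjust:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=30))
    @settings(max_examples=150, deadline=None)
    def test_bounds_and_sorted_monotonicity(self, ps):
        q = bh_adjust(ps)
        assert q.min() >= min(ps) - 1e-12
        assert q.max() <= 1.0 + 1e-12
        q_sorted = bh_adjust(sorted(ps))
        assert np.all(np.diff(q_sorted) >= -1e-12)

    def test_out_of_range_p_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])


def _oriented(dosage):
    dosage = np.asarray(dosage, dtype=float)
    return OrientedGenotypes(
        [f"s{i}" for i in range(dosage.shape[0])],
        [("1", j + 1, "A", "G") for j in range(dosage.shape[1])],
        dosage,
        np.zeros(dosage.shape[1]),
    )


class TestCooccurrence:
    def test_all_carriers_saturates_at_one(self):
        m = carrier_cooccurrence(_oriented(np.full((4, 3), 2.0)))
        np.testing.assert_array_equal(m.values, 1.0)

    def test_hand_example_one_joint_carrier_of_four(self):
        D = np.array([[1, 0], [2, 1], [0, 2], [0, 0]], dtype=float)
        m = carrier_cooccurrence(_oriented(D))
        assert m.values[0, 1] == pytest.approx(0.25)
        assert m.values[0, 0] == pytest.approx(0.5)  # diagonal = carrier prop

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(8)
        D = rng.integers(0, 3, size=(25, 10)).astype(float)
        D[rng.random(D.shape) < 0.1] = np.nan
        m = carrier_cooccurrence(_oriented(D))
        carriers = [
            {i for i in range(25) if D[i, j] >= 1} for j in range(10)
        ]
        for a in range(10):
            for b in range(10):
                assert m.values[a, b] == pytest.approx(
                    len(carriers[a] & carriers[b]) / 25
                )

    def test_pair_value_bounded_by_marginals(self):
        rng = np.random.default_rng(1)
        D = rng.integers(0, 3, size=(30, 8)).astype(float)
        m = carrier_cooccurrence(_oriented(D))
        diag = np.diag(m.values)
        assert np.all(m.values <= np.minimum.outer(diag, diag) + 1e-12)

    def test_difference_antisymmetric_and_bounded(self):
        rng = np.random.default_rng(2)
        A = _oriented(rng.integers(0, 3, size=(12, 5)).astype(float))
        B = _oriented(rng.integers(0, 3, size=(20, 5)).astype(float))
        ca, cb = carrier_cooccurrence(A), carrier_cooccurrence(B)
        d1 = cooccurrence_difference(ca, cb)
        d2 = cooccurrence_difference(cb, ca)
        np.testing.assert_allclose(d1.values, -d2.values, atol=1e-12)
        assert np.all(np.abs(d1.values) <= 1.0)

    def test_identical_cohorts_difference_is_zero(self):
        D = np.array([[1, 0], [0, 2]], dtype=float)
        c = carrier_cooccurrence(_oriented(D))
        np.testing.assert_array_equal(
            cooccurrence_difference(c, c).values, 0.0
        )

    def test_extreme_bound(self):
        case = carrier_cooccurrence(_oriented(np.full((3, 2), 2.0)))
        ctrl = carrier_cooccurrence(_oriented(np.zeros((5, 2))))
        np.testing.assert_array_equal(
            cooccurrence_difference(case, ctrl).values, 1.0
        )

    def test_variant_mismatch_raises(self):
        a = carrier_cooccurrence(_oriented(np.zeros((2, 2))))
        o = _oriented(np.zeros((2, 2)))
        o.variant_keys = [("2", 1, "A", "G"), ("2", 2, "A", "G")]
        b = carrier_cooccurrence(o)
        with pytest.raises(ValueError):
            cooccurrence_difference(a, b)
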