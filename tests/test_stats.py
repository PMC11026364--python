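"""Unit and property tests for the nonparametric/statistical primitives."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_
from scipy import stats as sps

from tracequant.stats import (
    _sign_sum_counts,
    bh_adjust,
    fit_lme_two_group,
    rank_sum_test,
    signed_rank_test,
    star_level,
)


class TestRankSum:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            (range(1, 6), range(6, 11), 2 / 252),  # complete separation 5 vs 5
            (range(1, 5), range(5, 10), 2 / 126),  # complete separation 4 vs 5
            ([1.0], [2.0], 1.0),  # 1-vs-1 two-sided floor
        ],
    )
    def test_exact_two_sided_values(self, x, y, expected):
        res = rank_sum_test(list(x), list(y))
        assert res.method == "exact_enumeration"
        assert res.p_two_sided == pytest.approx(expected, abs=1e-15)

    def test_agrees_with_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n1, n2 = rng.integers(2, 8, size=2)
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            mine = rank_sum_test(x, y).p_two_sided
            ref = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_symmetry_in_sample_order(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.integers(0, 5, size=5).astype(float)
            y = rng.integers(0, 5, size=7).astype(float)
            a, b = rank_sum_test(x, y), rank_sum_test(y, x)
            assert a.p_two_sided == pytest.approx(b.p_two_sided, abs=1e-12)
            assert a.direction == -b.direction

    def test_invariant_under_monotone_transformation(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(size=6)
            y = rng.normal(size=4)
            p0 = rank_sum_test(x, y).p_two_sided
            for f in (np.exp, lambda v: v**3, lambda v: 10 * v + 2):
                assert rank_sum_test(f(x), f(y)).p_two_sided == pytest.approx(p0, abs=1e-12)

    def test_normal_approximation_path(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=40)
        y = rng.normal(0.3, 1.0, size=45)
        res = rank_sum_test(x, y, max_exact_assignments=1000)
        ref = sps.mannwhitneyu(x, y, method="asymptotic", alternative="two-sided",
                               use_continuity=True).pvalue
        assert res.method == "normal_approx_tie_corrected"
        assert res.p_two_sided == pytest.approx(ref, rel=1e-6)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestSignedRank:
    def test_all_zero_differences_degenerate(self):
        res = signed_rank_test(np.zeros(8))
        assert res.p_two_sided == 1.0
        assert res.method == "zero_difference_degenerate"
        assert res.direction == 0

    def test_extreme_tail_closed_form(self):
        res = signed_rank_test(np.arange(1.0, 21.0))
        assert res.p_two_sided == pytest.approx(2 / 2**20, abs=1e-18)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            d = rng.normal(size=9)
            a, b = signed_rank_test(d), signed_rank_test(-d)
            assert a.p_two_sided == pytest.approx(b.p_two_sided, abs=1e-12)
            assert a.direction == -b.direction

    def test_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            d = rng.normal(size=rng.integers(3, 15))
            mine = signed_rank_test(d).p_two_sided
            ref = sps.wilcoxon(d, mode="exact").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("n", [1, 5, 12, 20])
    def test_null_distribution_mass_is_2_to_n(self, n):
        counts = _sign_sum_counts(2 * np.arange(1, n + 1))
        assert counts.sum() == 2**n  # float64 holds these integers exactly

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            signed_rank_test([])


class TestBH:
    def test_textbook_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_fixed_point_and_single(self):
        p = np.full(5, 0.3)  # constant vectors are step-up fixed points
        assert bh_adjust(p) == pytest.approx(p)
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    @given(st_.lists(st_.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_dominates_raw_and_rank_monotone(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


@pytest.mark.parametrize(
    "p, stars",
    [(0.2, "ns"), (0.06, "ns"), (0.05, "*"), (0.0118, "*"), (0.009, "**"),
     (0.0009, "***"), (0.00005, "****")],
)
def test_star_ladder(p, stars):
    assert star_level(p) == stars


class TestLME:
    @staticmethod
    def _simulate(rng, beta1=0.0, sigma_u=0.0, sigma=1.0, n_animals=5, n_meas=20):
        vals, ids, grp = [], [], []
        for gi, g in enumerate("AB"):
            for a in range(n_animals):
                u = rng.normal(0.0, sigma_u) if sigma_u > 0 else 0.0
                m = gi * beta1 + u + rng.normal(0.0, sigma, n_meas)
                vals += list(m)
                ids += [f"{g}{a}"] * n_meas
                grp += [g] * n_meas
        return np.array(vals), np.array(ids), np.array(grp)

    def test_reduces_to_ols_without_between_animal_variance(self):
        rng = np.random.default_rng(1)
        vals, ids, grp = self._simulate(rng, beta1=2.0, sigma_u=0.0)
        fit = fit_lme_two_group(vals, ids, grp)
        raw_diff = vals[grp == "B"].mean() - vals[grp == "A"].mean()
        assert fit.beta1 == pytest.approx(raw_diff, abs=3 * fit.se_beta1)
        assert fit.sigma2_u == pytest.approx(0.0, abs=1e-4)

    def test_parameter_recovery_with_random_intercepts(self):
        estimates = []
        for rep in range(30):
            rng = np.random.default_rng(100 + rep)
            vals, ids, grp = self._simulate(rng, beta1=50.0, sigma_u=200.0,
                                            sigma=400.0, n_animals=10, n_meas=100)
            estimates.append(fit_lme_two_group(vals, ids, grp).beta1)
        # unbiased around the generative effect; MC error shrinks with reps
        assert np.mean(estimates) == pytest.approx(50.0, rel=0.5)

    def test_relabeling_flips_sign_same_z(self):
        rng = np.random.default_rng(2)
        vals, ids, grp = self._simulate(rng, beta1=1.0, sigma_u=0.5)
        a = fit_lme_two_group(vals, ids, grp)
        flipped = np.where(grp == "A", "Z", "A")  # swaps which level sorts second
        b = fit_lme_two_group(vals, ids, flipped)
        assert b.beta1 == pytest.approx(-a.beta1, rel=1e-4)
        assert abs(b.beta1 / b.se_beta1) == pytest.approx(abs(a.beta1 / a.se_beta1), rel=1e-4)

    def test_design_errors(self):
        with pytest.raises(ValueError):
            fit_lme_two_group([1, 2, 3, 4], ["a", "a", "b", "b"], ["A", "A", "B", "B"])
        with pytest.raises(ValueError):
            fit_lme_two_group(np.ones(8), list("aabbccdd"), list("AABB") + list("BBAA"))
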