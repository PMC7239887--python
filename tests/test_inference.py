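"""Tests for the OLS comparison, likelihood-ratio and permutation machinery."""

import itertools
import math

import numpy as np
import pytest

from gmvnet.inference import (compare_models, fit_ols, likelihood_ratio_test,
                              perm_corr_test, perm_meandiff_test)
from gmvnet.preprocess import ColumnMeta, EncodedMatrix

from _oracles import ols_normal_equations


class TestOLS:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        fit = fit_ols(x, 2 * x)
        assert fit.coef == pytest.approx([0.0, 2.0], abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert np.isfinite(fit.loglik)  # RSS floor guards the log

    def test_intercept_only_is_mean(self, rng):
        y = rng.standard_normal(30) + 5
        fit = fit_ols(np.empty((30, 0)), y)
        assert fit.coef[0] == pytest.approx(y.mean())
        assert fit.n_params == 1

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((40, 3))
        y = X @ [1.0, -0.5, 2.0] + rng.standard_normal(40)
        fit = fit_ols(X, y)
        assert np.max(np.abs(fit.coef - ols_normal_equations(X, y))) < 1e-10

    def test_rank_deficient_rejected(self, rng):
        x = rng.standard_normal(20)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_ols(np.column_stack([x, 2 * x]), rng.standard_normal(20))


class TestLRT:
    def test_df_counts_parameter_difference(self, rng):
        X = rng.standard_normal((50, 4))
        y = X @ [1, 0.5, -0.5, 0.2] + rng.standard_normal(50)
        full = fit_ols(X, y)
        reduced = fit_ols(X[:, :1], y)
        stat, df, p = likelihood_ratio_test(full, reduced)
        assert df == 3
        assert stat >= 0
        assert stat == pytest.approx(2 * (full.loglik - reduced.loglik))

    def test_equal_models_give_zero_and_p_one(self, rng):
        X = rng.standard_normal((30, 2))
        y = rng.standard_normal(30)
        a, b = fit_ols(X, y), fit_ols(X.copy(), y)
        b.n_params = a.n_params - 1  # pretend nesting with identical RSS
        stat, _, p = likelihood_ratio_test(a, b)
        assert stat == 0.0 and p == 1.0

    def test_non_nested_rejected(self, rng):
        X = rng.standard_normal((30, 2))
        y = rng.standard_normal(30)
        with pytest.raises(ValueError, match="not nested"):
            likelihood_ratio_test(fit_ols(X[:, :1], y), fit_ols(X, y))

    def test_power_with_planted_signal(self):
        # extra predictors carry real signal at n = 264: the LRT should
        # reject in nearly all simulated training sets
        rng = np.random.default_rng(8)
        rejections = 0
        for _ in range(100):
            X = rng.standard_normal((264, 4))
            y = (0.9 * X[:, 0] + 0.25 * X[:, 1] - 0.2 * X[:, 2]
                 - 0.15 * X[:, 3] + rng.standard_normal(264))
            _, _, p = likelihood_ratio_test(fit_ols(X, y), fit_ols(X[:, :1], y))
            rejections += p < 0.05
        assert rejections >= 95


class TestCompareModels:
    @staticmethod
    def _matrix(rng, n=160):
        X = rng.standard_normal((n, 4))
        y = 1.0 * X[:, 0] + 0.5 * X[:, 1] + rng.standard_normal(n)
        cols = [ColumnMeta(name=n_, source=n_)
                for n_ in ("age", "gfr", "diabetes", "noise")]
        return EncodedMatrix(X=X, y=y, columns=cols)

    def test_full_model_beats_baseline(self, rng):
        m = self._matrix(rng)
        rep = compare_models(m, ["age", "gfr"], ["age"], n_splits=100, seed=2)
        assert rep.mean_mse_a < rep.mean_mse_b
        assert np.mean(rep.lrt_p < 0.05) > 0.9

    def test_identical_variable_sets_give_identical_metrics(self, rng):
        m = self._matrix(rng)
        rep = compare_models(m, ["age"], ["age"], n_splits=20, seed=3)
        assert np.array_equal(rep.mse_a, rep.mse_b)
        assert np.all(rep.lrt_stat == 0) and np.all(rep.lrt_p == 1)

    def test_deterministic_under_seed(self, rng):
        m = self._matrix(rng)
        a = compare_models(m, ["age", "gfr"], ["age"], n_splits=25, seed=4)
        b = compare_models(m, ["age", "gfr"], ["age"], n_splits=25, seed=4)
        assert np.array_equal(a.lrt_p, b.lrt_p)
        assert np.array_equal(a.mse_a, b.mse_a)

    def test_histogram_covers_unit_interval(self, rng):
        m = self._matrix(rng)
        rep = compare_models(m, ["age", "gfr"], ["age"], n_splits=50, seed=5)
        counts, edges = rep.p_histogram(bins=10)
        assert counts.sum() == 50
        assert edges[0] == 0.0 and edges[-1] == 1.0

    def test_non_nested_baseline_rejected(self, rng):
        m = self._matrix(rng)
        with pytest.raises(ValueError, match="nest"):
            compare_models(m, ["age", "gfr"], ["noise"], n_splits=5, seed=1)


class TestPermCorr:
    def test_exhaustive_monotone_pair(self):
        # x = y = [1,2,3,4]: of the 24 orderings only the identity and the
        # reversal attain |r| = 1, so p = (1 + 2) / (1 + 24)
        res = perm_corr_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.exhaustive
        assert res.observed == pytest.approx(1.0)
        assert res.p_value == pytest.approx(3 / 25)

    def test_exhaustive_matches_direct_enumeration(self, rng):
        x = rng.standard_normal(6)
        y = 0.8 * x + 0.5 * rng.standard_normal(6)
        res = perm_corr_test(x, y)
        r_obs = np.corrcoef(x, y)[0, 1]
        count = sum(
            abs(np.corrcoef(x, np.asarray(perm))[0, 1]) >= abs(r_obs) - 1e-12
            for perm in itertools.permutations(y))
        assert res.p_value == pytest.approx((1 + count) / (1 + math.factorial(6)))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            perm_corr_test([1, 2, 3, 4], [5, 5, 5, 5])

    def test_random_mode_deterministic_under_seed(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        a = perm_corr_test(x, y, n_permutations=500, seed=9)
        b = perm_corr_test(x, y, n_permutations=500, seed=9)
        assert not a.exhaustive
        assert a.p_value == b.p_value

    def test_strong_correlation_small_p(self, rng):
        x = np.linspace(0, 1, 50)
        y = x + 0.05 * rng.standard_normal(50)
        res = perm_corr_test(x, y, n_permutations=2000, seed=1)
        assert res.p_value <= 1 / 2001 + 1e-12


class TestPermMeanDiff:
    def test_identical_groups_p_one(self):
        res = perm_meandiff_test([1.0, 2.0], [1.0, 2.0])
        assert res.observed == 0.0 and res.p_value == 1.0

    def test_exhaustive_two_vs_two(self):
        # [0,0] vs [1,1]: of the C(4,2)=6 assignments, |diff| = 1 for the
        # original labelling and its swap -> p = (1+2)/(1+6)
        res = perm_meandiff_test([0.0, 0.0], [1.0, 1.0])
        assert res.exhaustive
        assert res.p_value == pytest.approx(3 / 7)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            perm_meandiff_test([], [1.0])

    def test_null_p_values_super_uniform(self):
        # validity: under H0, P(p <= t) <= t (small simulation; the full
        # type-I-error check runs in the acceptance suite)
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(400):
            a = rng.standard_normal(12)
            b = rng.standard_normal(12)
            ps.append(perm_meandiff_test(a, b, n_permutations=99,
                                         seed=int(rng.integers(2**31))).p_value)
        ps = np.asarray(ps)
        for t in (0.01, 0.05, 0.1):
            assert np.mean(ps <= t) <= t + 2.5 * np.sqrt(t * (1 - t) / 400)
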