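"""Unit and property tests for the coordinate-descent elastic net."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmvnet.elastic_net import (CrossValidatedElasticNet, ElasticNetCD,
                                adjusted_r2, cross_validate_lambda,
                                fit_elastic_net, kkt_residual, lambda_grid,
                                mse, objective_value, soft_threshold,
                                standardize)
from gmvnet._cd import cd_gram

from _oracles import prox_grad_elastic_net, ridge_closed_form


def _random_instance(rng, n=30, p=5, snr=1.0):
    X = rng.standard_normal((n, p)) @ (
        np.eye(p) + 0.3 * rng.standard_normal((p, p)))
    beta = rng.standard_normal(p) * snr
    y = X @ beta + rng.standard_normal(n)
    Xs, _, _ = standardize(X)
    return Xs, y


# ---------------------------------------------------------------- primitives

@pytest.mark.parametrize("z,g,expected", [
    (3.0, 1.0, 2.0),
    (-0.5, 1.0, 0.0),
    (-2.5, 1.0, -1.5),
    (0.0, 0.0, 0.0),
])
def test_soft_threshold_values(z, g, expected):
    assert soft_threshold(z, g) == pytest.approx(expected)


def test_soft_threshold_rejects_negative_gamma():
    with pytest.raises(ValueError):
        soft_threshold(1.0, -0.1)


@settings(derandomize=True, max_examples=100)
@given(z=st.floats(-1e6, 1e6), g=st.floats(0, 1e6))
def test_soft_threshold_shrinks_toward_zero(z, g):
    s = soft_threshold(z, g)
    assert abs(s) <= abs(z)
    assert s * z >= 0  # never flips sign
    if abs(z) > g:
        assert abs(s) == pytest.approx(abs(z) - g, abs=1e-9)


def test_standardize_moments_and_idempotence(rng):
    X = rng.standard_normal((50, 4)) * [1, 10, 0.1, 3] + [5, -2, 0, 1]
    Xs, means, scales = standardize(X)
    assert np.allclose(Xs.mean(axis=0), 0, atol=1e-12)
    assert np.allclose(np.mean(Xs**2, axis=0), 1, atol=1e-12)
    Xs2, _, _ = standardize(Xs)
    assert np.allclose(Xs2, Xs, atol=1e-12)


def test_standardize_names_zero_variance_column(rng):
    X = np.column_stack([rng.standard_normal(20), np.full(20, 3.0)])
    with pytest.raises(ValueError, match="const"):
        standardize(X, names=["ok", "const"])


@pytest.mark.parametrize("pred,truth,expected", [
    ([1.0, 2.0], [2.0, 4.0], 2.5),
    ([3.0, 3.0], [3.0, 3.0], 0.0),
])
def test_mse_values(pred, truth, expected):
    assert mse(pred, truth) == pytest.approx(expected)


def test_mse_constant_offset_is_squared(rng):
    y = rng.standard_normal(40)
    assert mse(y + 0.7, y) == pytest.approx(0.49)


def test_mse_length_mismatch():
    with pytest.raises(ValueError):
        mse([1.0], [1.0, 2.0])


def test_adjusted_r2_formula_and_edges(rng):
    # R^2 = 0.5, n = 11, p = 1 -> 1 - 0.5 * 10/9
    y = np.arange(11, dtype=float)
    sst = np.sum((y - y.mean()) ** 2)
    resid = rng.standard_normal(11)
    resid -= resid.mean()
    pred = y - resid * np.sqrt(0.5 * sst / (resid @ resid))
    assert adjusted_r2(pred, y, 1) == pytest.approx(1 - 0.5 * 10 / 9)
    assert adjusted_r2(y, y, 3) == pytest.approx(1.0)
    # p = 0 reduces to plain R^2
    r2 = 1 - np.sum((y - pred) ** 2) / sst
    assert adjusted_r2(pred, y, 0) == pytest.approx(r2)
    with pytest.raises(ValueError):
        adjusted_r2(pred, y, 10)
    with pytest.raises(ValueError):
        adjusted_r2(np.ones(5), np.ones(5), 0)


# -------------------------------------------------------------------- solver

def test_univariate_closed_form():
    # single standardized predictor with (1/n) x'y = 0.5:
    # beta = S(0.5, lam*alpha) / (1 + lam*(1-alpha)) = S(0.5, 0.1)/1.1
    n = 40
    x = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
    y = 0.5 * x
    fit = fit_elastic_net(x[:, None], y, alpha=0.5, lam=0.2)
    assert fit.coef[0] == pytest.approx(0.4 / 1.1, abs=1e-9)


def test_lambda_zero_recovers_ols(rng):
    Xs, y = _random_instance(rng)
    fit = fit_elastic_net(Xs, y, alpha=0.5, lam=0.0, tol=1e-13,
                          max_iter=200_000)
    ols = np.linalg.lstsq(np.column_stack([np.ones(len(y)), Xs]), y,
                          rcond=None)[0]
    assert np.max(np.abs(fit.coef - ols[1:])) < 1e-8


def test_lasso_null_solution_at_lambda_max(rng):
    Xs, y = _random_instance(rng)
    lam_max = float(np.abs(Xs.T @ (y - y.mean()) / len(y)).max())
    fit = fit_elastic_net(Xs, y, alpha=1.0, lam=lam_max * (1 + 1e-12))
    assert np.all(fit.coef == 0)


def test_ridge_limit_matches_closed_form(rng):
    Xs, y = _random_instance(rng)
    for lam in (0.05, 0.5, 3.0):
        fit = fit_elastic_net(Xs, y, alpha=0.0, lam=lam, tol=1e-13,
                              max_iter=200_000)
        assert np.max(np.abs(fit.coef - ridge_closed_form(Xs, y, lam))) < 1e-8


def test_matches_proximal_gradient_oracle(rng):
    for _ in range(10):
        Xs, y = _random_instance(rng)
        alpha = rng.uniform(0.05, 1.0)
        lam = rng.uniform(0.01, 0.5)
        fit = fit_elastic_net(Xs, y, alpha=alpha, lam=lam, tol=1e-12,
                              max_iter=100_000)
        oracle = prox_grad_elastic_net(Xs, y, alpha, lam)
        assert np.max(np.abs(fit.coef - oracle)) < 1e-6


def test_matches_sklearn_cross_check(rng):
    from sklearn.linear_model import ElasticNet as SkEN

    Xs, y = _random_instance(rng, n=80, p=10)
    fit = fit_elastic_net(Xs, y, alpha=0.3, lam=0.2, tol=1e-12,
                          max_iter=100_000)
    sk = SkEN(alpha=0.2, l1_ratio=0.3, tol=1e-12, max_iter=200_000).fit(Xs, y)
    assert np.max(np.abs(fit.coef - sk.coef_)) < 1e-7


def test_kkt_residual_small_at_convergence(rng):
    for _ in range(5):
        Xs, y = _random_instance(rng)
        fit = fit_elastic_net(Xs, y, alpha=0.4, lam=0.15, tol=1e-10)
        assert fit.converged
        assert kkt_residual(Xs, y, fit) <= 1e-7


def test_objective_nonincreasing_per_sweep(rng):
    Xs, y = _random_instance(rng, n=50, p=8)
    n = len(y)
    G, c = Xs.T @ Xs / n, Xs.T @ (y - y.mean()) / n
    beta = np.zeros(8)
    prev = np.inf
    for _ in range(30):
        cd_gram(G, c, beta, 0.2, 0.5, 0.0, 1)  # exactly one sweep
        obj = objective_value(Xs, y, y.mean(), beta, 0.5, 0.2)
        assert obj <= prev + 1e-12
        prev = obj


def test_sparsity_monotone_in_lambda_for_lasso():
    # independent-column designs: the lasso active set only shrinks as the
    # penalty grows (correlated designs can legitimately violate this)
    for seed in range(5):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((60, 12))
        y = X @ rng.standard_normal(12) + rng.standard_normal(60)
        Xs, _, _ = standardize(X)
        grid = lambda_grid(Xs, y, alpha=1.0, n_values=40)
        nnz = []
        for lam in grid[::-1]:  # increasing lambda
            fit = fit_elastic_net(Xs, y, alpha=1.0, lam=lam)
            nnz.append(int(np.sum(np.abs(fit.coef) > 1e-10)))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))


def test_nonconvergence_flag_and_warning(rng):
    Xs, y = _random_instance(rng)
    with pytest.warns(RuntimeWarning, match="did not converge"):
        fit = fit_elastic_net(Xs, y, alpha=0.5, lam=0.01, tol=1e-14,
                              max_iter=2)
    assert not fit.converged


# --------------------------------------------------------------- lambda grid

def test_lambda_grid_scaling_and_shape(rng):
    # single column with (1/n) x'y = 0.5 at alpha 0.2 -> lam_max = 2.5
    n = 40
    x = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
    y = 0.5 * x
    grid = lambda_grid(x[:, None], y, alpha=0.2, n_values=100)
    assert grid[0] == pytest.approx(2.5)
    assert grid.shape == (100,)
    assert np.all(np.diff(grid) < 0)
    assert grid[-1] == pytest.approx(2.5e-4)
    single = lambda_grid(x[:, None], y, alpha=0.2, n_values=1)
    assert single.tolist() == [pytest.approx(2.5)]


def test_lambda_grid_alpha_floor(rng):
    Xs, y = _random_instance(rng)
    g0 = lambda_grid(Xs, y, alpha=0.0)
    g_floor = lambda_grid(Xs, y, alpha=0.001)
    assert g0[0] == pytest.approx(g_floor[0])


# ----------------------------------------------------------- cross-validation

def test_cv_deterministic_under_seed(rng):
    Xs, y = _random_instance(rng, n=60, p=6)
    a = cross_validate_lambda(Xs, y, 0.2, k=5, seed=42)
    b = cross_validate_lambda(Xs, y, 0.2, k=5, seed=42)
    assert np.array_equal(a.mean_cv_mse, b.mean_cv_mse)
    assert a.lambda_min == b.lambda_min and a.lambda_1se == b.lambda_1se


def test_cv_rejects_too_many_folds(rng):
    Xs, y = _random_instance(rng, n=8, p=2)
    with pytest.raises(ValueError):
        cross_validate_lambda(Xs, y, 0.2, k=9)


def test_cv_pure_noise_prefers_heavy_penalty():
    # on pure-noise outcomes the argmin should sit near the top of the grid
    # (the null model) in the clear majority of repetitions
    rng = np.random.default_rng(7)
    near_top = 0
    reps = 30
    for _ in range(reps):
        X = rng.standard_normal((80, 10))
        y = rng.standard_normal(80)
        Xs, _, _ = standardize(X)
        cv = cross_validate_lambda(Xs, y, 0.2, k=5, seed=1)
        k = int(np.argmin(cv.mean_cv_mse))
        near_top += k <= 25
    assert near_top >= reps * 0.6


def test_cv_strong_predictor_selected_at_lambda_min():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((200, 5))
    y = 2.0 * X[:, 0] + 0.3 * rng.standard_normal(200)
    Xs, _, _ = standardize(X)
    cv = cross_validate_lambda(Xs, y, 0.2, k=10, seed=5)
    fit = fit_elastic_net(Xs, y, 0.2, cv.lambda_min)
    assert fit.coef[0] != 0
    assert cv.lambda_1se >= cv.lambda_min


# ---------------------------------------------------------------- estimators

def test_estimator_original_scale_roundtrip(rng):
    X = rng.standard_normal((100, 4)) * [2, 0.5, 7, 1] + [10, -3, 0, 4]
    y = X @ [1.0, -2.0, 0.0, 0.5] + 0.1 * rng.standard_normal(100)
    est = ElasticNetCD(alpha=0.5, lam=1e-6, tol=1e-12).fit(X, y)
    assert np.allclose(est.predict(X), y, atol=0.5)
    assert est.selected_.sum() >= 3


def test_estimator_sklearn_protocol(rng):
    from sklearn.base import clone

    est = ElasticNetCD(alpha=0.3, lam=0.2)
    params = est.get_params()
    assert params["alpha"] == 0.3
    est2 = clone(est).set_params(lam=0.5)
    assert est2.lam == 0.5
    X = rng.standard_normal((50, 3))
    y = rng.standard_normal(50)
    assert est.fit(X, y).predict(X).shape == (50,)


def test_cv_estimator_rules(rng):
    X = rng.standard_normal((120, 6))
    y = 1.5 * X[:, 0] - X[:, 1] + 0.5 * rng.standard_normal(120)
    est = CrossValidatedElasticNet(alpha=0.2, n_folds=5, rule="1se",
                                   random_state=0).fit(X, y)
    assert est.lambda_ == est.lambda_1se_ >= est.lambda_min_
    assert set(np.nonzero(est.selected_)[0]) >= {0, 1}
    est_min = CrossValidatedElasticNet(alpha=0.2, n_folds=5, rule="min",
                                       random_state=0).fit(X, y)
    assert est_min.lambda_ == est_min.lambda_min_
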