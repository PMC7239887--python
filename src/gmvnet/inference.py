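"""Follow-up analyses: unpenalized nested-model comparison and permutation tests.

After the elastic net has ranked variables, two unpenalized linear models
are compared over fresh 90/10 splits: (a) the selected predictors and
(b) age only.  Per split both are fitted on the training rows, a Gaussian
likelihood-ratio test is computed on the training fit, and held-out MSE and
adjusted R^2 are recorded.  Note this routine is over-optimistic in
absolute terms (the variable set was chosen on the same underlying data);
only the a-vs-b comparison is meaningful.

Marginal associations are tested by permutation (default 20 000 draws,
exhaustive enumeration when the exact null is smaller), with the add-one
rule p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm), so p is never 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .elastic_net import adjusted_r2, mse
from .preprocess import EncodedMatrix
from .stability import make_splits

__all__ = [
    "OLSFit",
    "PermutationResult",
    "ComparisonReport",
    "fit_ols",
    "likelihood_ratio_test",
    "compare_models",
    "perm_corr_test",
    "perm_meandiff_test",
]

_RSS_FLOOR = 1e-12  # keeps the Gaussian log-likelihood finite on noiseless toys


def _nanmean_or_nan(x) -> float:
    x = np.asarray(x, dtype=float)
    ok = ~np.isnan(x)
    return float(x[ok].mean()) if ok.any() else float("nan")


@dataclass
class OLSFit:
    """Ordinary least squares fit with Gaussian log-likelihood."""

    coef: np.ndarray        # [intercept, slopes...]
    rss: float
    n: int
    n_params: int           # including the intercept
    loglik: float


@dataclass
class PermutationResult:
    observed: float
    n_permutations: int
    p_value: float
    kind: str               # "pearson_r" or "mean_difference"
    seed: int | None
    exhaustive: bool = False


@dataclass
class ComparisonReport:
    """Per-split LRT and held-out metrics for models a (full) and b (reduced)."""

    n_splits: int
    lrt_stat: np.ndarray
    lrt_p: np.ndarray
    mse_a: np.ndarray
    mse_b: np.ndarray
    adj_r2_a: np.ndarray
    adj_r2_b: np.ndarray

    @property
    def mean_mse_a(self) -> float:
        return float(np.mean(self.mse_a))

    @property
    def mean_mse_b(self) -> float:
        return float(np.mean(self.mse_b))

    @property
    def mean_adj_r2_a(self) -> float:
        return _nanmean_or_nan(self.adj_r2_a)

    @property
    def mean_adj_r2_b(self) -> float:
        return _nanmean_or_nan(self.adj_r2_b)

    def p_histogram(self, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
        """Histogram bin counts of the per-split LRT p-values on [0, 1]."""
        counts, edges = np.histogram(self.lrt_p, bins=bins, range=(0.0, 1.0))
        return counts, edges

    def summary(self) -> dict:
        return {
            "n_splits": self.n_splits,
            "mean_mse_full": self.mean_mse_a,
            "mean_mse_baseline": self.mean_mse_b,
            "mean_adj_r2_full": self.mean_adj_r2_a,
            "mean_adj_r2_baseline": self.mean_adj_r2_b,
            "frac_lrt_p_below_0.05": float(np.mean(self.lrt_p < 0.05)),
        }


def fit_ols(X, y) -> OLSFit:
    """Least squares with intercept; rank-deficient designs are an error.

    loglik = -(n/2) (log(2 pi RSS/n) + 1), the Gaussian profile likelihood.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.shape[0]
    D = np.column_stack([np.ones(n), X])
    if n <= D.shape[1] - 1:
        raise ValueError(f"n={n} too small for {D.shape[1]} parameters")
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        raise ValueError("rank-deficient design")
    coef, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    r = y - D @ coef
    rss = float(r @ r)
    loglik = -0.5 * n * (math.log(2 * math.pi * max(rss, _RSS_FLOOR) / n) + 1)
    return OLSFit(coef=coef, rss=rss, n=n, n_params=D.shape[1], loglik=loglik)


def likelihood_ratio_test(full: OLSFit, reduced: OLSFit):
    """LRT of nested Gaussian linear models fitted to the same data.

    statistic = 2 (l_full - l_reduced) = n log(RSS_reduced / RSS_full);
    df = parameter-count difference; p from the chi-square upper tail.
    """
    if full.n != reduced.n:
        raise ValueError("models fitted on different data (n differs)")
    if full.n_params <= reduced.n_params:
        raise ValueError("models not nested: full must have more parameters")
    stat = full.n * math.log(max(reduced.rss, _RSS_FLOOR) / max(full.rss, _RSS_FLOOR))
    stat = max(stat, 0.0)
    df = full.n_params - reduced.n_params
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def compare_models(matrix: EncodedMatrix, selected_vars, baseline_vars=("age",),
                   n_splits: int = 1000, test_fraction: float = 0.1,
                   seed: int | None = None) -> ComparisonReport:
    """Fresh-split comparison of OLS on ``selected_vars`` vs ``baseline_vars``.

    New splits (independent of the elastic-net loop) are drawn from ``seed``;
    both models are fitted on the training rows, the LRT is computed on the
    training fit, and MSE / adjusted R^2 on the held-out rows.  When the two
    variable sets coincide the models are identical and the LRT is skipped
    (statistic 0, p 1).
    """
    names = matrix.column_names
    def _cols(vs):
        idx = []
        for v in vs:
            if v in names:
                idx.append(names.index(v))
            else:
                hit = matrix.columns_of(v)
                if not hit:
                    raise ValueError(f"variable {v!r} not in matrix")
                idx.extend(hit)
        return idx

    ia, ib = _cols(selected_vars), _cols(baseline_vars)
    same = set(ia) == set(ib)
    if not same and not set(ib).issubset(ia):
        raise ValueError("baseline variables must nest within the selected set")
    splits = make_splits(matrix.y.shape[0], n_splits=n_splits,
                         test_fraction=test_fraction, seed=seed)
    stat = np.zeros(n_splits)
    pval = np.ones(n_splits)
    msea = np.zeros(n_splits)
    mseb = np.zeros(n_splits)
    ra = np.full(n_splits, np.nan)
    rb = np.full(n_splits, np.nan)
    for i, s in enumerate(splits):
        ytr, yte = matrix.y[s.train], matrix.y[s.test]
        Xa_tr, Xa_te = matrix.X[s.train][:, ia], matrix.X[s.test][:, ia]
        Xb_tr, Xb_te = matrix.X[s.train][:, ib], matrix.X[s.test][:, ib]
        fa = fit_ols(Xa_tr, ytr)
        fb = fa if same else fit_ols(Xb_tr, ytr)
        if not same:
            stat[i], _, pval[i] = likelihood_ratio_test(fa, fb)
        pa = fa.coef[0] + Xa_te @ fa.coef[1:]
        pb = fb.coef[0] + Xb_te @ fb.coef[1:]
        msea[i], mseb[i] = mse(pa, yte), mse(pb, yte)
        nte = yte.shape[0]
        if nte > len(ia) + 1:
            ra[i] = adjusted_r2(pa, yte, len(ia))
        if nte > len(ib) + 1:
            rb[i] = adjusted_r2(pb, yte, len(ib))
    return ComparisonReport(n_splits=n_splits, lrt_stat=stat, lrt_p=pval,
                            mse_a=msea, mse_b=mseb, adj_r2_a=ra, adj_r2_b=rb)


def _pearson_r(x, y):
    return float(np.corrcoef(x, y)[0, 1])


def perm_corr_test(x, y, n_permutations: int = 20_000,
                   seed: int | None = None) -> PermutationResult:
    """Two-sided permutation test of the Pearson correlation.

    y is permuted; exhaustive enumeration over all n! orderings is used
    automatically when n! <= n_permutations, otherwise ``n_permutations``
    seeded random permutations with the add-one counting rule.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 3 or y.shape[0] != n:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = x - x.mean()
    xs = xc / np.sqrt(xc @ xc)
    yc = y - y.mean()
    ys = yc / np.sqrt(yc @ yc)
    r_obs = float(xs @ ys)
    eps = 1e-12
    if math.factorial(n) <= n_permutations:
        perms = np.array(list(itertools.permutations(range(n))))
        r_all = np.abs(ys[perms] @ xs)
        count = int(np.sum(r_all >= abs(r_obs) - eps))
        total = perms.shape[0]
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_permutations, n)), axis=1)
        r_perm = np.abs(ys[idx] @ xs)
        count = int(np.sum(r_perm >= abs(r_obs) - eps))
        total = n_permutations
        exhaustive = False
    p = (1 + count) / (1 + total)
    return PermutationResult(observed=r_obs, n_permutations=total, p_value=p,
                             kind="pearson_r", seed=seed, exhaustive=exhaustive)


def perm_meandiff_test(group_a, group_b, n_permutations: int = 20_000,
                       seed: int | None = None) -> PermutationResult:
    """Two-sided permutation test of a difference in group means.

    Group labels are permuted; exhaustive enumeration over all C(n, n_a)
    label assignments is used when that count is <= n_permutations.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    na, n = a.size, a.size + b.size
    d_obs = float(a.mean() - b.mean())
    eps = 1e-12
    n_comb = math.comb(n, na)
    if n_comb <= n_permutations:
        diffs = np.empty(n_comb)
        total_sum = pooled.sum()
        for i, idx in enumerate(itertools.combinations(range(n), na)):
            sa = pooled[list(idx)].sum()
            diffs[i] = sa / na - (total_sum - sa) / (n - na)
        count = int(np.sum(np.abs(diffs) >= abs(d_obs) - eps))
        total = n_comb
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_permutations, n)), axis=1)
        shuffled = pooled[idx]
        diffs = shuffled[:, :na].mean(axis=1) - shuffled[:, na:].mean(axis=1)
        count = int(np.sum(np.abs(diffs) >= abs(d_obs) - eps))
        total = n_permutations
        exhaustive = False
    p = (1 + count) / (1 + total)
    return PermutationResult(observed=d_obs, n_permutations=total, p_value=p,
                             kind="mean_difference", seed=seed,
                             exhaustive=exhaustive)
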