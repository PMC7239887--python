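"""Outer resampling loop: repeated train/test splits, per-split nested CV.

The importance measure is selection frequency: over S independent random
90/10 train/test splits (default S = 1000), an elastic net is fitted on
each training set with its penalty strength chosen by an inner 10-fold CV,
and a variable counts as selected when its coefficient is nonzero.  Per
split the fitted model is scored on the held-out 10% (MSE, adjusted R^2),
alongside the Null Model that always predicts the training mean —
the minimum bound of predictive performance (MSE_0).

Standardization statistics are computed on training rows only and applied
to the test rows; anything else would leak test information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._cd import cd_path
from .elastic_net import (SELECTION_EPS, CVResult, cross_validate_lambda,
                          lambda_grid, mse)
from .preprocess import EncodedMatrix

__all__ = [
    "SplitSpec",
    "SplitResult",
    "StabilityReport",
    "make_splits",
    "run_split",
    "null_model_mse",
    "run_stability",
    "alpha_sweep",
    "StabilitySelector",
]

#: default selection-count threshold for the "most predictive" reporting subset
REPORT_THRESHOLD = 100


@dataclass(frozen=True)
class SplitSpec:
    split_index: int
    train: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self):
        if np.intersect1d(self.train, self.test).size:
            raise ValueError("train and test overlap")


@dataclass
class SplitResult:
    split_index: int
    selected: np.ndarray        # bool mask over encoded columns
    coef: np.ndarray            # original-scale coefficients
    lambda_min: float
    test_mse: float
    test_adj_r2: float          # nan when undefined (too many selected for n_test)
    null_mse: float


@dataclass
class StabilityReport:
    """Aggregate of the outer resampling loop at one alpha."""

    alpha: float
    n_splits: int
    variables: list[str]
    selection_count: np.ndarray
    mean_coef_selected: np.ndarray  # mean original-scale beta over splits where selected
    mean_test_mse: float
    mean_adj_r2: float
    mean_lambda: float
    null_mse: float                 # MSE_0, mean over splits
    report_threshold: int = REPORT_THRESHOLD

    @property
    def selection_frequency(self) -> np.ndarray:
        return self.selection_count / self.n_splits

    def most_predictive(self) -> list[str]:
        """Variables selected in at least ``report_threshold`` splits."""
        return [v for v, c in zip(self.variables, self.selection_count)
                if c >= self.report_threshold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": self.variables,
            "selection_count": self.selection_count,
            "selection_frequency": self.selection_frequency,
            "mean_beta": self.mean_coef_selected,
        }).sort_values("selection_count", ascending=False, kind="stable",
                       ignore_index=True)

    def summary(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_splits": self.n_splits,
            "mean_test_mse": self.mean_test_mse,
            "null_mse": self.null_mse,
            "mean_adj_r2": self.mean_adj_r2,
            "mean_lambda": self.mean_lambda,
            "most_predictive": self.most_predictive(),
        }


def make_splits(n: int, n_splits: int = 1000, test_fraction: float = 0.1,
                seed: int | None = None) -> list[SplitSpec]:
    """Seeded independent train/test splits; test size = floor(fraction * n).

    n = 293 at the default fraction gives train 264 / test 29.
    """
    n_test = int(np.floor(test_fraction * n))
    if n_test < 1:
        raise ValueError(f"test size 0 for n={n}, fraction={test_fraction}")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_splits)
    splits = []
    for i in range(n_splits):
        rng = np.random.default_rng(child_seeds[i])
        perm = rng.permutation(n)
        splits.append(SplitSpec(split_index=i,
                                test=np.sort(perm[:n_test]),
                                train=np.sort(perm[n_test:]),
                                seed=int(child_seeds[i])))
    return splits


def null_model_mse(train_outcome, test_outcome) -> float:
    """Test MSE of the constant prediction mean(train_outcome)."""
    train_outcome = np.asarray(train_outcome, dtype=float)
    test_outcome = np.asarray(test_outcome, dtype=float)
    if train_outcome.size == 0 or test_outcome.size == 0:
        raise ValueError("empty outcome vector")
    return mse(np.full(test_outcome.shape, train_outcome.mean()), test_outcome)


def _train_standardize(X):
    """Training-rows standardization tolerant of zero-variance columns.

    Columns constant in the training rows get scale 1 and are excluded from
    the model (their coefficient is pinned at 0 by a zero Gram diagonal).
    """
    means = X.mean(axis=0)
    Xc = X - means
    scales = np.sqrt(np.mean(Xc * Xc, axis=0))
    dead = scales <= 0
    scales = np.where(dead, 1.0, scales)
    return Xc / scales, means, scales, dead


def run_split(matrix: EncodedMatrix, split: SplitSpec, alpha: float,
              n_folds: int = 10, n_lambdas: int = 100,
              lambda_min_ratio: float = 1e-4, rule: str = "1se",
              tol: float = 1e-7, max_iter: int = 10_000) -> SplitResult:
    """One outer split: inner CV for lambda, refit on the training set,
    score on the held-out rows.

    ``rule`` picks the penalty from the inner CV curve: "1se" (default, the
    one-standard-error rule, parsimonious) or "min" (curve argmin)."""
    try:
        Xtr, ytr = matrix.X[split.train], matrix.y[split.train]
        Xte, yte = matrix.X[split.test], matrix.y[split.test]
        Xs, means, scales, dead = _train_standardize(Xtr)
        if dead.any():
            Xs[:, dead] = 0.0
        grid = lambda_grid(Xs, ytr, alpha, n_values=n_lambdas,
                           ratio=lambda_min_ratio)
        cv = cross_validate_lambda(Xs, ytr, alpha, k=n_folds,
                                   seed=split.seed, grid=grid, tol=tol,
                                   max_iter=max_iter)
        k_min = cv.index_of(rule)
        lam_used = float(grid[k_min])
        n = ytr.shape[0]
        G = (Xs.T @ Xs) / n
        c = Xs.T @ (ytr - ytr.mean()) / n
        betas, _, _ = cd_path(G, c, grid[: k_min + 1], alpha, tol, max_iter)
        beta_std = betas[-1]
        coef = beta_std / scales
        coef[dead] = 0.0
        selected = np.abs(coef) > SELECTION_EPS
        intercept = float(ytr.mean() - coef @ means)
        pred = intercept + Xte @ coef
        test_mse = mse(pred, yte)
        p_sel = int(selected.sum())
        n_test = yte.shape[0]
        if n_test > p_sel + 1:
            sst = float(np.sum((yte - yte.mean()) ** 2))
            if sst > 0:
                r2 = 1.0 - float(np.sum((yte - pred) ** 2)) / sst
                adj = 1.0 - (1.0 - r2) * (n_test - 1) / (n_test - p_sel - 1)
            else:
                adj = np.nan
        else:
            adj = np.nan
        return SplitResult(split_index=split.split_index, selected=selected,
                           coef=coef, lambda_min=lam_used,
                           test_mse=test_mse, test_adj_r2=adj,
                           null_mse=null_model_mse(ytr, yte))
    except Exception as exc:  # noqa: BLE001 - annotate with the split index
        raise RuntimeError(f"split {split.split_index} failed: {exc}") from exc


def _aggregate(matrix: EncodedMatrix, alpha: float, results: list[SplitResult],
               report_threshold: int) -> StabilityReport:
    n_splits = len(results)
    sel = np.vstack([r.selected for r in results])
    coefs = np.vstack([r.coef for r in results])
    counts = sel.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_beta = np.where(
            counts > 0,
            np.where(sel, coefs, 0.0).sum(axis=0) / np.maximum(counts, 1),
            0.0,
        )
    adj = np.array([r.test_adj_r2 for r in results])
    return StabilityReport(
        alpha=alpha,
        n_splits=n_splits,
        variables=matrix.column_names,
        selection_count=counts,
        mean_coef_selected=mean_beta,
        mean_test_mse=float(np.mean([r.test_mse for r in results])),
        mean_adj_r2=float(np.nanmean(adj)) if np.any(~np.isnan(adj)) else float("nan"),
        mean_lambda=float(np.mean([r.lambda_min for r in results])),
        null_mse=float(np.mean([r.null_mse for r in results])),
        report_threshold=report_threshold,
    )


def run_stability(matrix: EncodedMatrix, alpha: float = 0.2,
                  n_splits: int = 1000, test_fraction: float = 0.1,
                  seed: int | None = None, n_folds: int = 10,
                  n_lambdas: int = 100, lambda_min_ratio: float = 1e-4,
                  rule: str = "1se",
                  report_threshold: int = REPORT_THRESHOLD,
                  splits: list[SplitSpec] | None = None) -> StabilityReport:
    """Run the full outer loop and aggregate into a StabilityReport."""
    if splits is None:
        splits = make_splits(matrix.y.shape[0], n_splits=n_splits,
                             test_fraction=test_fraction, seed=seed)
    results = [run_split(matrix, s, alpha, n_folds=n_folds,
                         n_lambdas=n_lambdas,
                         lambda_min_ratio=lambda_min_ratio, rule=rule)
               for s in splits]
    return _aggregate(matrix, alpha, results, report_threshold)


def alpha_sweep(matrix: EncodedMatrix, alphas=None, n_splits: int = 1000,
                test_fraction: float = 0.1, seed: int | None = None,
                **kwargs) -> list[StabilityReport]:
    """One StabilityReport per alpha; the same split list is reused across
    alphas so differences isolate the mixing weight."""
    if alphas is None:
        alphas = np.round(np.arange(0.0, 0.201, 0.01), 2)
    splits = make_splits(matrix.y.shape[0], n_splits=n_splits,
                         test_fraction=test_fraction, seed=seed)
    return [run_stability(matrix, alpha=float(a), splits=splits, **kwargs)
            for a in alphas]


class StabilitySelector(BaseEstimator):
    """Selection-frequency variable ranking via repeated-split elastic nets.

    Parameters mirror :func:`run_stability`; after ``fit(X, y)`` (or
    ``fit(matrix)`` with an :class:`EncodedMatrix`) the report lives in
    fitted attributes.

    Attributes (after fit)
    ----------------------
    report_ : StabilityReport
    selection_count_, selection_frequency_, mean_coef_ : per-column arrays
    mean_test_mse_, null_mse_, mean_adj_r2_, mean_lambda_ : scalars
    """

    def __init__(self, alpha=0.2, n_splits=1000, test_fraction=0.1,
                 n_folds=10, n_lambdas=100, lambda_min_ratio=1e-4,
                 rule="1se", report_threshold=REPORT_THRESHOLD,
                 random_state=None):
        self.alpha = alpha
        self.n_splits = n_splits
        self.test_fraction = test_fraction
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.rule = rule
        self.report_threshold = report_threshold
        self.random_state = random_state

    def fit(self, X, y=None, feature_names=None):
        from .preprocess import ColumnMeta

        if isinstance(X, EncodedMatrix):
            matrix = X
        else:
            X = np.asarray(X, dtype=float)
            names = (list(feature_names) if feature_names is not None
                     else [f"x{j}" for j in range(X.shape[1])])
            matrix = EncodedMatrix(
                X=X, y=np.asarray(y, dtype=float),
                columns=[ColumnMeta(name=nm, source=nm) for nm in names])
        report = run_stability(
            matrix, alpha=self.alpha, n_splits=self.n_splits,
            test_fraction=self.test_fraction, seed=self.random_state,
            n_folds=self.n_folds, n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio, rule=self.rule,
            report_threshold=self.report_threshold)
        self.report_ = report
        self.feature_names_ = report.variables
        self.selection_count_ = report.selection_count
        self.selection_frequency_ = report.selection_frequency
        self.mean_coef_ = report.mean_coef_selected
        self.mean_test_mse_ = report.mean_test_mse
        self.null_mse_ = report.null_mse
        self.mean_adj_r2_ = report.mean_adj_r2
        self.mean_lambda_ = report.mean_lambda
        self.n_features_in_ = matrix.X.shape[1]
        return self

    def get_support(self, threshold: int | None = None) -> np.ndarray:
        thr = self.report_threshold if threshold is None else threshold
        return self.selection_count_ >= thr
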