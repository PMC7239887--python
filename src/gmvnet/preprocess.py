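"""Prepare a cohort table for modelling: imputation and numeric encoding.

Missing predictors are completed by either column mean/mode filling or a
single pass of chained equations (iterated per-variable regressions on all
other predictors: linear for continuous, ridge-regularized logistic for
binary, linear-then-round for ordinal), producing one completed data set.
Blocks whose missingness exceeds a drop threshold are removed before
imputation, mirroring the exclusion of high-missingness questionnaire
blocks from the main analysis.

Encoding: continuous columns pass through, binary stay single 0/1 columns,
ordinal variables with k levels expand to k-1 dummies against the lowest
level as reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CohortTable

__all__ = ["EncodedMatrix", "ColumnMeta", "impute", "encode", "drop_high_missingness"]


@dataclass(frozen=True)
class ColumnMeta:
    name: str       # encoded column name
    source: str     # source predictor
    level: float | None = None  # dummy level for ordinal expansions


@dataclass
class EncodedMatrix:
    """Fully numeric design matrix plus outcome, as consumed by the models."""

    X: np.ndarray
    y: np.ndarray
    columns: list[ColumnMeta]

    def __post_init__(self):
        if np.isnan(self.X).any():
            raise ValueError("encoded matrix contains missing values")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column metadata length mismatch")

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def columns_of(self, source: str) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.source == source]


def drop_high_missingness(table: CohortTable, threshold: float = 0.3) -> CohortTable:
    """Drop whole blocks whose mean predictor missingness exceeds ``threshold``."""
    frac = table.predictor_frame().isna().mean()
    block_frac = frac.groupby(table.schema["block"]).mean()
    dropped = set(block_frac.index[block_frac > threshold])
    if not dropped:
        return table
    keep = [v for v in table.predictors if table.schema.loc[v, "block"] not in dropped]
    df = table.df[[table.outcome] + keep]
    return CohortTable(df=df, schema=table.schema.loc[keep].copy(),
                       outcome=table.outcome).validate()


def _mean_mode_fill(df: pd.DataFrame, schema: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for name in schema.index:
        col = out[name]
        if not col.isna().any():
            continue
        if schema.loc[name, "vtype"] == "continuous":
            out[name] = col.fillna(col.mean())
        else:
            out[name] = col.fillna(col.mode().iloc[0])
    return out


def _logistic_irls(X, y, ridge=1e-3, n_iter=25):
    """Ridge-stabilized logistic regression by IRLS; X includes the intercept."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-6)
        H = X.T @ (X * w[:, None]) + ridge * np.eye(X.shape[1])
        g = X.T @ (y - p) - ridge * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def _linear_draw(rng, Xobs, yobs, Xmis, ridge=1e-6):
    A = Xobs.T @ Xobs + ridge * np.eye(Xobs.shape[1])
    beta = np.linalg.solve(A, Xobs.T @ yobs)
    resid = yobs - Xobs @ beta
    dof = max(len(yobs) - Xobs.shape[1], 1)
    sigma = np.sqrt(resid @ resid / dof)
    return Xmis @ beta + sigma * rng.standard_normal(Xmis.shape[0])


def impute(table: CohortTable, method: str = "chained", n_cycles: int = 5,
           seed: int | None = None) -> CohortTable:
    """Complete missing predictor values; observed cells are never altered.

    method "mean_mode": column mean (continuous) / mode (binary, ordinal).
    method "chained": mean/mode initialization, then ``n_cycles`` passes of
    per-variable regressions on all other predictors with stochastic draws
    (normal residual draw for continuous, Bernoulli for binary, rounded and
    clipped linear draw for ordinal).  Deterministic under a fixed seed.
    """
    if method not in ("mean_mode", "chained"):
        raise ValueError(f"unknown imputation method {method!r}")
    df = table.df
    preds = table.predictors
    all_missing = [v for v in preds if df[v].isna().all()]
    if all_missing:
        raise ValueError(f"column {all_missing[0]!r} is entirely missing")
    na = df[preds].isna()
    if not na.any().any():
        return table

    filled = _mean_mode_fill(df, table.schema)
    if method == "mean_mode":
        return CohortTable(df=filled, schema=table.schema.copy(),
                           outcome=table.outcome).validate()

    rng = np.random.default_rng(seed)
    work = filled[preds].to_numpy(dtype=float)
    orig = df[preds].to_numpy(dtype=float)
    na_arr = na.to_numpy()
    vtypes = [table.schema.loc[v, "vtype"] for v in preds]
    targets = [j for j in range(len(preds)) if na_arr[:, j].any()]
    levels = {
        j: (np.nanmin(orig[:, j]), np.nanmax(orig[:, j]))
        for j in targets if vtypes[j] == "ordinal"
    }
    for _ in range(n_cycles):
        for j in targets:
            mis = na_arr[:, j]
            obs = ~mis
            others = np.delete(np.arange(len(preds)), j)
            Xo = np.column_stack([np.ones(obs.sum()), work[obs][:, others]])
            Xm = np.column_stack([np.ones(mis.sum()), work[mis][:, others]])
            yo = work[obs, j]
            if vtypes[j] == "binary":
                beta = _logistic_irls(Xo, yo)
                p = 1.0 / (1.0 + np.exp(-np.clip(Xm @ beta, -30, 30)))
                work[mis, j] = (rng.random(mis.sum()) < p).astype(float)
            else:
                draw = _linear_draw(rng, Xo, yo, Xm)
                if vtypes[j] == "ordinal":
                    lo, hi = levels[j]
                    draw = np.clip(np.round(draw), lo, hi)
                work[mis, j] = draw
    out = df.copy()
    out[preds] = work
    # invariant: observed cells unchanged
    out[preds] = out[preds].where(na, df[preds])
    return CohortTable(df=out, schema=table.schema.copy(),
                       outcome=table.outcome).validate()


def encode(table: CohortTable) -> EncodedMatrix:
    """Encode a complete cohort table into a numeric design matrix.

    Raises if any predictor still has missing values or an unknown type tag.
    """
    df = table.df
    if df[table.predictors].isna().any().any():
        raise ValueError("encode requires a complete table; impute first")
    cols: list[np.ndarray] = []
    meta: list[ColumnMeta] = []
    for name in table.predictors:
        vtype = table.schema.loc[name, "vtype"]
        x = df[name].to_numpy(dtype=float)
        if vtype in ("continuous", "binary"):
            cols.append(x)
            meta.append(ColumnMeta(name=name, source=name))
        elif vtype == "ordinal":
            lvls = np.unique(x)
            for lv in lvls[1:]:  # lowest level is the reference
                cols.append((x == lv).astype(float))
                meta.append(ColumnMeta(name=f"{name}={lv:g}", source=name, level=float(lv)))
        else:
            raise ValueError(f"unknown type tag {vtype!r} for column {name!r}")
    X = np.column_stack(cols) if cols else np.empty((df.shape[0], 0))
    y = df[table.outcome].to_numpy(dtype=float)
    return EncodedMatrix(X=X, y=y, columns=meta)
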