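"""Descriptive statistics, pipeline configuration and end-to-end orchestration.

``run_pipeline`` chains the stages: synthesize (or load) a cohort, inject
and impute missingness, encode, run the stability-selection loop, then the
unpenalized comparison and permutation follow-ups, writing all artifacts
(TSV/JSON plus a log of seeds and versions) into an output directory.
Identical configuration and seeds give byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import compare_models, perm_corr_test, perm_meandiff_test
from .preprocess import drop_high_missingness, encode, impute
from .stability import REPORT_THRESHOLD, run_stability
from .synthetic import (CohortTable, SyntheticPreset, generate_cohort,
                        inject_missingness, kora_like_preset,
                        pure_noise_preset)

__all__ = ["PipelineConfig", "describe", "run_pipeline"]

log = logging.getLogger(__name__)

_PRESETS = {"kora_like": kora_like_preset, "pure_noise": pure_noise_preset}


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    preset: str | None = "kora_like"     # or None with cohort_path set
    cohort_path: str | None = None
    schema_path: str | None = None
    alpha: float = 0.2
    n_splits: int = 1000
    n_folds: int = 10
    test_fraction: float = 0.1
    seed: int = 0
    imputation: str = "chained"
    imputation_cycles: int = 5
    missingness_drop_threshold: float = 0.3
    apply_missingness: bool = False      # inject the preset's MCAR rates
    #: selection-count threshold for the "most predictive" subset; None
    #: scales the published rule (>= 100 of 1000 splits) to n_splits
    report_threshold: int | None = None
    comparison_baseline: tuple[str, ...] = ("age",)
    n_permutations: int = 20_000
    out_dir: str = "gmvnet_out"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_splits < 1 or self.n_folds < 2:
            raise ValueError("n_splits >= 1 and n_folds >= 2 required")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.preset is None and self.cohort_path is None:
            raise ValueError("either preset or cohort_path is required")

    def to_yaml(self, path):
        doc = dataclasses.asdict(self)
        doc["comparison_baseline"] = list(self.comparison_baseline)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "comparison_baseline" in doc:
            doc["comparison_baseline"] = tuple(doc["comparison_baseline"])
        return cls(**doc)


def describe(table: CohortTable) -> pd.DataFrame:
    """Descriptive table: mean +/- SD and median [Q1, Q3] for continuous
    variables, counts and percentages for categorical ones."""
    rows = []
    df = table.df
    variables = [table.outcome] + table.predictors
    for name in variables:
        vtype = ("continuous" if name == table.outcome
                 else table.schema.loc[name, "vtype"])
        col = df[name].dropna()
        n = int(col.size)
        if vtype == "continuous":
            mean = col.mean() if n else np.nan
            sd = col.std(ddof=1) if n > 1 else np.nan
            q1, med, q3 = (col.quantile([0.25, 0.5, 0.75])
                           if n else (np.nan,) * 3)
            rows.append({
                "variable": name, "type": vtype, "n": n,
                "summary": (f"{mean:.2f} ± {sd:.2f}" if n > 1
                            else ("NA" if n == 0 else f"{mean:.2f} ± NA")),
                "median_iqr": (f"{med:.2f} [{q1:.2f}, {q3:.2f}]" if n else "NA"),
            })
        else:
            counts = col.value_counts().sort_index()
            parts = [f"{lvl:g}: {c} ({100 * c / n:.0f}%)"
                     for lvl, c in counts.items()] if n else ["NA"]
            rows.append({"variable": name, "type": vtype, "n": n,
                         "summary": "; ".join(parts), "median_iqr": ""})
    return pd.DataFrame(rows)


def _load_cohort(config: PipelineConfig) -> CohortTable:
    if config.cohort_path is not None:
        if config.schema_path is None:
            raise FileNotFoundError("schema_path required with cohort_path")
        for p in (config.cohort_path, config.schema_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")
        return CohortTable.from_tsv(config.cohort_path, config.schema_path)
    if config.preset not in _PRESETS:
        raise ValueError(f"unknown preset {config.preset!r}")
    preset: SyntheticPreset = _PRESETS[config.preset]()
    table = generate_cohort(preset, seed=config.seed)
    if config.apply_missingness:
        table = inject_missingness(table, preset.missing_rates,
                                   seed=config.seed + 1)
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the summary dict written to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    stage = "load"
    try:
        table = _load_cohort(config)
        describe(table).to_csv(out / "descriptives.tsv", sep="\t", index=False)

        stage = "preprocess"
        table = drop_high_missingness(table, config.missingness_drop_threshold)
        n_missing = int(table.predictor_frame().isna().sum().sum())
        table = impute(table, method=config.imputation,
                       n_cycles=config.imputation_cycles, seed=config.seed + 2)
        matrix = encode(table)

        stage = "stability"
        threshold = (config.report_threshold
                     if config.report_threshold is not None
                     else max(1, round(REPORT_THRESHOLD / 1000 * config.n_splits)))
        report = run_stability(
            matrix, alpha=config.alpha, n_splits=config.n_splits,
            test_fraction=config.test_fraction, seed=config.seed + 3,
            n_folds=config.n_folds, report_threshold=threshold)
        report.to_frame().to_csv(out / "stability_report.tsv", sep="\t",
                                 index=False)

        stage = "comparison"
        top = report.most_predictive()
        baseline = [v for v in config.comparison_baseline
                    if any(c.source == v or c.name == v for c in matrix.columns)]
        summary: dict = {
            "version": __version__,
            "config": {**dataclasses.asdict(config),
                       "comparison_baseline": list(config.comparison_baseline)},
            "n_subjects": int(table.df.shape[0]),
            "n_predictors": len(table.predictors),
            "n_missing_cells_imputed": n_missing,
            "stability": report.summary(),
        }
        selected_sources = sorted({matrix.columns[j].source
                                   for j, v in enumerate(report.variables)
                                   if report.selection_count[j] >= threshold})
        if baseline and set(baseline).issubset(selected_sources) \
                and len(selected_sources) > len(baseline):
            comp = compare_models(matrix, selected_sources, baseline,
                                  n_splits=config.n_splits,
                                  test_fraction=config.test_fraction,
                                  seed=config.seed + 4)
            summary["comparison"] = comp.summary()
            counts, edges = comp.p_histogram()
            pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                          "count": counts}).to_csv(
                out / "lrt_p_histogram.tsv", sep="\t", index=False)
        else:
            log.info("comparison skipped: baseline not nested in selected set")

        stage = "permutation"
        perms = {}
        y = table.df[table.outcome].to_numpy()
        for v in top:
            src = v.split("=")[0]
            if src not in table.df.columns:
                continue
            x = table.df[src].to_numpy(dtype=float)
            if table.schema.loc[src, "vtype"] == "binary":
                res = perm_meandiff_test(y[x == 1], y[x == 0],
                                         n_permutations=config.n_permutations,
                                         seed=config.seed + 5)
            else:
                res = perm_corr_test(x, y,
                                     n_permutations=config.n_permutations,
                                     seed=config.seed + 5)
            perms[src] = {"kind": res.kind, "observed": res.observed,
                          "p_value": res.p_value,
                          "n_permutations": res.n_permutations}
        summary["permutation_tests"] = perms

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        config.to_yaml(out / "config.yaml")
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
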