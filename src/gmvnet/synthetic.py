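"""Synthetic cohort generator for the GMV-determinants analysis.

The real study population (a population-based MRI sub-cohort, n = 293, with
93 mixed-type candidate determinants of ICV-adjusted gray matter volume) is
available only on request, so every downstream stage is exercised on
synthetic cohorts that reproduce the statistical structure the inference
relies on:

* blockwise-correlated predictors (sociodemographics, anthropometrics,
  cardio-metabolic, diabetes-related, lifestyle, medication, sleep, labs,
  somatic symptoms), generated as equicorrelated Gaussian latents per block
  and transformed to continuous / skewed (log-normal) / binary / ordinal
  variables;
* four planted linear determinants — age, glomerular filtration rate (GFR),
  diabetes status and diabetes duration — whose direct coefficients are
  calibrated so that the *marginal* associations match the published ones
  (Pearson r = -0.67 for age, +0.37 for GFR, a -0.9 percentage-point shift
  for diabetes at 11.9% prevalence, r = -0.15 for diabetes duration);
* an outcome (ICV-adjusted GMV, in % of intracranial volume) with mean 20.5
  and total SD 1.3, Gaussian residual noise making up the unexplained part;
* optional missing-completely-at-random masking per block.

Calibration converts the marginal targets t into direct coefficients by
solving beta_std = sigma_y * R^-1 t, where R is the correlation matrix of
the planted predictors.  Age and GFR live in different blocks and are
independent of the diabetes pair, so the solve factorizes; the
diabetes/duration sub-block has no convenient closed form (thresholded and
zero-inflated log-normal margins), so its moments are estimated once from a
large fixed-seed draw of the generator's own marginals.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "VariableSpec",
    "BlockSpec",
    "SyntheticPreset",
    "CohortTable",
    "kora_like_preset",
    "pure_noise_preset",
    "generate_cohort",
    "inject_missingness",
]

OUTCOME = "gmv_icv_pct"


@dataclass(frozen=True)
class VariableSpec:
    """One predictor variable.

    vtype: "continuous", "binary" or "ordinal".
    transform: "none" (mean + sd * z), "exp" (exp(mean + sd * z), skewed) or
    "duration" (indicator-gated capped log-normal; ``duration_of`` names the
    binary gate, ``mean``/``sd`` are the log-scale location/scale and ``cap``
    the upper truncation).
    """

    name: str
    vtype: str = "continuous"
    mean: float = 0.0
    sd: float = 1.0
    prevalence: float | None = None
    n_levels: int | None = None
    transform: str = "none"
    duration_of: str | None = None
    cap: float | None = None
    #: optional cross-block latent loading (ref_variable, r): the latent
    #: becomes r * z_ref + sqrt(1 - r^2) * z_own, so corr(z, z_ref) = r.
    #: The reference must be generated earlier.
    corr_with: tuple[str, float] | None = None

    def __post_init__(self):
        if self.vtype not in ("continuous", "binary", "ordinal"):
            raise ValueError(f"unknown vtype {self.vtype!r} for {self.name}")
        if self.vtype == "binary":
            if self.prevalence is None or not 0 < self.prevalence < 1:
                raise ValueError(f"binary {self.name} needs prevalence in (0,1)")
        if self.vtype == "ordinal":
            if self.n_levels is None or self.n_levels < 2:
                raise ValueError(f"ordinal {self.name} needs n_levels >= 2")
        if self.transform == "duration" and self.duration_of is None:
            raise ValueError(f"duration variable {self.name} needs duration_of")

    def population_mean(self) -> float:
        """Closed-form population mean where one exists (duration has none)."""
        if self.vtype == "binary":
            return float(self.prevalence)
        if self.vtype == "ordinal":
            return (self.n_levels - 1) / 2.0  # equiprobable levels 0..k-1
        if self.transform == "exp":
            return float(np.exp(self.mean + 0.5 * self.sd**2))
        if self.transform == "duration":
            raise ValueError(f"{self.name}: no closed-form mean for duration")
        return self.mean


@dataclass(frozen=True)
class BlockSpec:
    """A named block of variables sharing an equicorrelated Gaussian latent."""

    name: str
    rho: float
    variables: tuple[VariableSpec, ...]

    def __post_init__(self):
        # equicorrelation with rho in [0, 1) is always positive definite
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(
                f"block {self.name}: within-block correlation must be in "
                f"[0, 1) for a positive-definite latent covariance, got {self.rho}")
        if len(self.variables) == 0:
            raise ValueError(f"block {self.name} is empty")


@dataclass
class SyntheticPreset:
    """Full parameterization of the cohort generator."""

    n_subjects: int
    blocks: tuple[BlockSpec, ...]
    planted_effects: dict[str, float]  # variable -> coefficient, outcome units per natural unit
    outcome_mean: float
    outcome_sd: float
    noise_sd: float
    missing_rates: dict[str, float] = field(default_factory=dict)
    rng_seed: int = 0
    planted_centers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        names = [v.name for b in self.blocks for v in b.variables]
        if len(names) != len(set(names)):
            raise ValueError("duplicate variable names across blocks")
        known = set(names)
        for v in self.planted_effects:
            if v not in known:
                raise ValueError(f"planted effect on unknown variable {v!r}")
        blocks = {b.name for b in self.blocks}
        for b, r in self.missing_rates.items():
            if b not in blocks:
                raise ValueError(f"missing rate for unknown block {b!r}")
            if not 0.0 <= r < 1.0:
                raise ValueError(f"missing rate for block {b!r} must be in [0,1)")
        if self.noise_sd < 0 or self.outcome_sd <= 0:
            raise ValueError("noise_sd must be >= 0 and outcome_sd > 0")

    @property
    def n_predictors(self) -> int:
        return sum(len(b.variables) for b in self.blocks)

    def variable_block(self) -> dict[str, str]:
        return {v.name: b.name for b in self.blocks for v in b.variables}

    def variable_specs(self) -> dict[str, VariableSpec]:
        return {v.name: v for b in self.blocks for v in b.variables}

    def to_yaml(self, path):
        doc = {
            "n_subjects": self.n_subjects,
            "outcome_mean": self.outcome_mean,
            "outcome_sd": self.outcome_sd,
            "noise_sd": self.noise_sd,
            "rng_seed": self.rng_seed,
            "planted_effects": {k: float(v) for k, v in self.planted_effects.items()},
            "planted_centers": {k: float(v) for k, v in self.planted_centers.items()},
            "missing_rates": {k: float(v) for k, v in self.missing_rates.items()},
            "blocks": [
                {
                    "name": b.name,
                    "rho": b.rho,
                    "variables": [
                        {k: v for k, v in vars(spec).items() if v is not None}
                        for spec in b.variables
                    ],
                }
                for b in self.blocks
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticPreset":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        blocks = tuple(
            BlockSpec(
                name=b["name"],
                rho=b["rho"],
                variables=tuple(VariableSpec(**v) for v in b["variables"]),
            )
            for b in doc["blocks"]
        )
        return cls(
            n_subjects=doc["n_subjects"],
            blocks=blocks,
            planted_effects=doc.get("planted_effects", {}),
            outcome_mean=doc["outcome_mean"],
            outcome_sd=doc["outcome_sd"],
            noise_sd=doc["noise_sd"],
            missing_rates=doc.get("missing_rates", {}),
            rng_seed=doc.get("rng_seed", 0),
            planted_centers=doc.get("planted_centers", {}),
        )


@dataclass
class CohortTable:
    """Per-subject cohort table: outcome plus typed predictors.

    ``df`` is indexed by subject id and holds the outcome column plus one
    column per predictor; ``schema`` maps each predictor to (vtype, block).
    """

    df: pd.DataFrame
    schema: pd.DataFrame  # index: variable name; columns: vtype, block
    outcome: str = OUTCOME

    def validate(self) -> "CohortTable":
        if self.outcome not in self.df.columns:
            raise ValueError(f"outcome column {self.outcome!r} missing")
        if self.df[self.outcome].isna().any():
            raise ValueError("outcome has missing values")
        if self.df.columns.duplicated().any():
            raise ValueError("duplicate column names")
        for name, row in self.schema.iterrows():
            if name not in self.df.columns:
                raise ValueError(f"schema variable {name!r} not in table")
            if row.vtype == "binary":
                vals = self.df[name].dropna().unique()
                if not set(np.asarray(vals)).issubset({0.0, 1.0}):
                    raise ValueError(f"binary column {name!r} not in {{0,1}}")
        return self

    @property
    def predictors(self) -> list[str]:
        return list(self.schema.index)

    def predictor_frame(self) -> pd.DataFrame:
        return self.df[self.predictors]

    def to_tsv(self, path, schema_path):
        self.df.to_csv(path, sep="\t", index_label="subject_id")
        self.schema.to_csv(schema_path, sep="\t", index_label="name")

    @classmethod
    def from_tsv(cls, path, schema_path, outcome=OUTCOME) -> "CohortTable":
        df = pd.read_csv(path, sep="\t", index_col="subject_id")
        schema = pd.read_csv(schema_path, sep="\t", index_col="name")
        return cls(df=df, schema=schema, outcome=outcome).validate()


# --------------------------------------------------------------------------
# the default cohort preset: a population-based MRI sub-cohort feature table
# --------------------------------------------------------------------------

_DIABETES_PREVALENCE = 0.119
_DURATION_LOG_MEDIAN = float(np.log(3.0))  # median ~3 y since diagnosis
_DURATION_LOG_SIGMA = 1.3                  # heavy right tail (new to ~decades)
_DURATION_CAP = 50.0
# cross-block structure among the planted determinants: kidney function
# declines with age, and diabetes is more prevalent at higher ages, so part
# of their marginal association with the outcome is shared with age
_AGE_GFR_CORR = -0.4
_AGE_DIABETES_LATENT_CORR = 0.25
_CALIBRATION_SEED = 20_200_520
_CALIBRATION_N = 200_000

_MARGINAL_TARGETS = {
    "age": -0.67,        # Pearson r with outcome
    "gfr": 0.37,         # Pearson r
    "diabetes": -0.9,    # mean outcome shift, percentage points (19.7 vs 20.6)
    "diabetes_duration": -0.15,  # Pearson r
}


def _c(name, mean, sd):
    return VariableSpec(name, "continuous", mean=mean, sd=sd)


def _e(name, logmean, logsd):
    return VariableSpec(name, "continuous", mean=logmean, sd=logsd, transform="exp")


def _b(name, prev):
    return VariableSpec(name, "binary", prevalence=prev)


def _o(name, k):
    return VariableSpec(name, "ordinal", n_levels=k)


def _kora_blocks() -> tuple[BlockSpec, ...]:
    return (
        BlockSpec("sociodemographics", 0.35, (
            _c("age", 55.4, 9.1),
            _b("sex_male", 0.59),
            _b("married", 0.70),
            _b("employed", 0.60),
            _o("education", 3),
            _o("income", 4),
            _c("household_size", 2.4, 1.1),
            _c("years_in_region", 30, 15),
            _c("social_support_score", 50, 10),
            _c("work_hours", 32, 14),
            _o("urbanicity", 3),
            _o("community_activity", 3),
        )),
        BlockSpec("anthropometric", 0.6, (
            _c("bmi", 27.9, 4.6),
            _c("waist_circ", 95, 13),
            _c("hip_circ", 104, 9),
            _c("weight", 80, 15),
            _c("height", 170, 9),
            _c("body_fat_pct", 30, 8),
            _c("waist_hip_ratio", 0.91, 0.08),
            _c("neck_circ", 38, 4),
            _e("subcut_fat_mri", 5.3, 0.4),
            _e("visceral_fat_mri", 1.5, 0.6),
        )),
        BlockSpec("cardiometabolic", 0.5, (
            _c("sbp", 120, 17),
            _c("dbp", 75, 10),
            _b("hypertension", 0.34),
            _c("pulse_pressure", 46, 12),
            _c("heart_rate", 68, 10),
            _c("total_chol", 218, 37),
            _c("ldl_chol", 140, 33),
            _c("hdl_chol", 60, 16),
            _e("triglycerides", 4.7, 0.5),
            _e("lipoprotein_a", 2.3, 1.0),
            _c("carotid_imt", 0.8, 0.15),
            _c("framingham_score", 8, 5),
            _b("metabolic_syndrome", 0.25),
            _c("uric_acid", 5.5, 1.3),
        )),
        BlockSpec("diabetes", 0.7, (
            VariableSpec("diabetes", "binary", prevalence=_DIABETES_PREVALENCE,
                         corr_with=("age", _AGE_DIABETES_LATENT_CORR)),
            VariableSpec("diabetes_duration", "continuous",
                         mean=_DURATION_LOG_MEDIAN, sd=_DURATION_LOG_SIGMA,
                         transform="duration", duration_of="diabetes",
                         cap=_DURATION_CAP),
            _c("hba1c", 5.6, 0.7),
            _c("fasting_glucose", 103, 20),
            _e("fasting_insulin", 2.3, 0.6),
            _e("homa_ir", 0.9, 0.7),
        )),
        BlockSpec("lifestyle", 0.3, (
            _b("smoker_current", 0.18),
            _b("smoker_former", 0.38),
            _e("alcohol_g_day", 2.2, 1.0),
            _o("physical_activity", 4),
            _c("sport_hours", 2.5, 2.0),
            _c("walking_min_day", 35, 25),
            _c("tv_hours", 2.5, 1.5),
            _c("coffee_cups", 2.8, 1.8),
            _c("fruit_veg_portions", 3.2, 1.5),
            _e("smoking_packyears", 1.8, 1.2),
            _c("diet_score", 50, 12),
            _b("active_commute", 0.30),
        )),
        BlockSpec("medication", 0.25, (
            _b("med_antihypertensive", 0.30),
            _b("med_statin", 0.12),
            _b("med_aspirin", 0.10),
            _b("med_thyroid", 0.12),
            _b("med_antidiabetic", 0.09),
            _b("med_nsaid", 0.15),
            _b("med_ppi", 0.10),
            _b("med_betablocker", 0.18),
            _b("med_diuretic", 0.12),
            _b("med_supplement", 0.25),
        )),
        BlockSpec("sleep", 0.4, (
            _c("sleep_duration", 7.1, 1.0),
            _e("sleep_latency_min", 2.7, 0.7),
            _o("sleep_problems", 3),
            _b("snoring", 0.42),
            _o("daytime_sleepiness", 3),
            _c("sleep_efficiency", 88, 6),
            _c("night_awakenings", 1.5, 1.1),
            _c("sleep_quality_score", 5, 3),
        )),
        BlockSpec("labs", 0.3, (
            VariableSpec("gfr", "continuous", mean=90, sd=15,
                         corr_with=("age", _AGE_GFR_CORR)),
            _c("creatinine", 0.85, 0.18),
            _c("urea", 32, 9),
            _e("crp", 0.0, 1.0),
            _c("hemoglobin", 14.4, 1.2),
            _c("leukocytes", 6.1, 1.5),
            _c("platelets", 240, 55),
            _e("alt", 3.2, 0.5),
            _e("ast", 3.1, 0.4),
            _e("ggt", 3.2, 0.7),
            _e("ferritin", 4.6, 0.9),
            _c("vitamin_d", 20, 8),
            _e("tsh", 0.3, 0.6),
            _c("albumin", 4.5, 0.3),
            _c("sodium", 140, 2.2),
        )),
        BlockSpec("somatic", 0.4, (
            _c("somatic_symptom_score", 5, 4),
            _o("headache_freq", 3),
            _o("back_pain", 3),
            _c("fatigue_score", 8, 5),
            _b("dizziness", 0.15),
            _o("general_health", 3),
        )),
    )


_DEFAULT_MISSING_RATES = {
    "sociodemographics": 0.01,
    "anthropometric": 0.01,
    "cardiometabolic": 0.03,
    "diabetes": 0.02,
    "lifestyle": 0.05,
    "medication": 0.02,
    "sleep": 0.08,
    "labs": 0.05,
    "somatic": 0.05,
}


@functools.lru_cache(maxsize=1)
def _calibrate_kora(outcome_sd=1.3):
    """Solve for the planted coefficients that hit the marginal targets.

    Returns (planted_effects natural scale, planted_centers, noise_sd).
    Deterministic: one large fixed-seed draw of the planted-variable joint
    (identical in law to the generator's output: the cross-block latent
    loadings of GFR and the diabetes indicator on age are reproduced, and
    everything else is independent of the planted set).
    """
    rng = np.random.default_rng(_CALIBRATION_SEED)
    n = _CALIBRATION_N
    z_age = rng.standard_normal(n)
    age = 55.4 + 9.1 * z_age
    a = _AGE_GFR_CORR
    z_gfr = a * z_age + np.sqrt(1 - a * a) * rng.standard_normal(n)
    gfr = 90 + 15 * z_gfr
    b = _AGE_DIABETES_LATENT_CORR
    z_d = b * z_age + np.sqrt(1 - b * b) * rng.standard_normal(n)
    diabetes = (z_d > stats.norm.ppf(1 - _DIABETES_PREVALENCE)).astype(float)
    w = rng.standard_normal(n)
    duration = diabetes * np.clip(
        np.exp(_DURATION_LOG_MEDIAN + _DURATION_LOG_SIGMA * w), 0.0,
        _DURATION_CAP)

    Xp = np.column_stack([age, gfr, diabetes, duration])
    mu = Xp.mean(axis=0)
    sd = Xp.std(axis=0)
    R = np.corrcoef(Xp, rowvar=False)

    sd_d = sd[2]
    targets = np.array([
        _MARGINAL_TARGETS["age"],
        _MARGINAL_TARGETS["gfr"],
        _MARGINAL_TARGETS["diabetes"] * sd_d / outcome_sd,  # shift -> point-biserial r
        _MARGINAL_TARGETS["diabetes_duration"],
    ])
    beta_std = outcome_sd * np.linalg.solve(R, targets)
    explained = outcome_sd**2 * float(targets @ np.linalg.solve(R, targets))
    resid_var = outcome_sd**2 - explained
    if resid_var <= 0:
        raise RuntimeError("marginal targets imply >100% explained variance")
    names = ["age", "gfr", "diabetes", "diabetes_duration"]
    effects = {nm: float(b / s) for nm, b, s in zip(names, beta_std, sd)}
    centers = {nm: float(m) for nm, m in zip(names, mu)}
    return effects, centers, float(np.sqrt(resid_var))


def kora_like_preset(n_subjects: int = 293) -> SyntheticPreset:
    """Default preset: 293 subjects, 93 blockwise-correlated predictors,
    planted age/GFR/diabetes/diabetes-duration effects calibrated to the
    published marginal associations, outcome 20.5 +/- 1.3 % ICV."""
    effects, centers, noise_sd = _calibrate_kora()
    return SyntheticPreset(
        n_subjects=n_subjects,
        blocks=_kora_blocks(),
        planted_effects=dict(effects),
        outcome_mean=20.5,
        outcome_sd=1.3,
        noise_sd=noise_sd,
        missing_rates=dict(_DEFAULT_MISSING_RATES),
        rng_seed=0,
        planted_centers=dict(centers),
    )


def pure_noise_preset(n_subjects: int = 293) -> SyntheticPreset:
    """Same feature table, no planted effects: outcome is pure Gaussian noise."""
    preset = kora_like_preset(n_subjects)
    return replace(preset, planted_effects={}, planted_centers={},
                   noise_sd=preset.outcome_sd)


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _generate_block(rng, block: BlockSpec, n: int, values: dict[str, np.ndarray],
                    latents: dict[str, np.ndarray]):
    """Draw one block: shared factor + idiosyncratic latents, then transform."""
    g = rng.standard_normal(n)
    sr, si = np.sqrt(block.rho), np.sqrt(1.0 - block.rho)
    for spec in block.variables:
        z = sr * g + si * rng.standard_normal(n)
        if spec.corr_with is not None:
            ref, r = spec.corr_with
            if ref not in latents:
                raise ValueError(
                    f"{spec.name}: corr_with reference {ref!r} must be "
                    "generated earlier")
            z = r * latents[ref] + np.sqrt(1.0 - r * r) * z
        latents[spec.name] = z
        if spec.transform == "duration":
            gate = values.get(spec.duration_of)
            if gate is None:
                raise ValueError(
                    f"{spec.name}: gate variable {spec.duration_of!r} must be "
                    "generated earlier in the same preset")
            # own independent draw: the only link to the block is the gate
            values[spec.name] = _duration_from(rng, gate, spec)
        elif spec.vtype == "binary":
            thr = stats.norm.ppf(1 - spec.prevalence)
            values[spec.name] = (z > thr).astype(float)
        elif spec.vtype == "ordinal":
            cuts = stats.norm.ppf(np.arange(1, spec.n_levels) / spec.n_levels)
            values[spec.name] = np.searchsorted(cuts, z).astype(float)
        elif spec.transform == "exp":
            values[spec.name] = np.exp(spec.mean + spec.sd * z)
        else:
            values[spec.name] = spec.mean + spec.sd * z


def _duration_from(rng, gate, spec: VariableSpec):
    w = rng.standard_normal(gate.shape[0])
    raw = np.exp(spec.mean + spec.sd * w)
    cap = spec.cap if spec.cap is not None else np.inf
    return gate * np.clip(raw, 0.0, cap)


def generate_cohort(preset: SyntheticPreset, seed: int | None = None) -> CohortTable:
    """Generate one cohort table; identical (preset, seed) gives identical output.

    outcome = outcome_mean + sum_j beta_j (x_j - E[x_j]) + N(0, noise_sd),
    so the population outcome mean is exactly ``outcome_mean``.
    """
    if seed is None:
        seed = preset.rng_seed
    rng = np.random.default_rng(seed)
    n = preset.n_subjects
    values: dict[str, np.ndarray] = {}
    latents: dict[str, np.ndarray] = {}
    for block in preset.blocks:
        _generate_block(rng, block, n, values, latents)

    specs = preset.variable_specs()
    y = np.full(n, float(preset.outcome_mean))
    for name, beta in preset.planted_effects.items():
        center = preset.planted_centers.get(name)
        if center is None:
            center = specs[name].population_mean()
        y = y + beta * (values[name] - center)
    if preset.noise_sd > 0:
        y = y + preset.noise_sd * rng.standard_normal(n)

    ids = [f"S{i + 1:04d}" for i in range(n)]
    cols = {OUTCOME: y}
    cols.update(values)
    df = pd.DataFrame(cols, index=pd.Index(ids, name="subject_id"))
    vb = preset.variable_block()
    schema = pd.DataFrame(
        {"vtype": [specs[v].vtype for v in values],
         "block": [vb[v] for v in values]},
        index=pd.Index(list(values), name="name"),
    )
    return CohortTable(df=df, schema=schema).validate()


def inject_missingness(table: CohortTable, rates: dict[str, float],
                       seed: int | None = None) -> CohortTable:
    """Mask predictor cells missing-completely-at-random, per-block rates.

    The outcome column is never masked; asking for it (or for an unknown
    block) is an error.
    """
    blocks = set(table.schema["block"])
    for b, r in rates.items():
        if b == table.outcome or b == OUTCOME:
            raise ValueError("outcome column cannot be masked")
        if b not in blocks:
            raise ValueError(f"missing rate for unknown block {b!r}")
        if not 0.0 <= r < 1.0:
            raise ValueError(f"rate for block {b!r} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    for name in table.predictors:
        rate = rates.get(table.schema.loc[name, "block"], 0.0)
        if rate > 0:
            mask = rng.random(df.shape[0]) < rate
            col = df[name].to_numpy(dtype=float, copy=True)
            col[mask] = np.nan
            df[name] = col
    return CohortTable(df=df, schema=table.schema.copy(), outcome=table.outcome).validate()
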