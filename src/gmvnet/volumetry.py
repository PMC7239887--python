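"""ICV-adjusted gray matter volume from compartment and region volume tables.

Intracranial volume (ICV) is the sum of gray matter, white matter and
cerebrospinal fluid; ratio correction expresses a volume as a percentage of
ICV.  Region-level volumes (AAL atlas vocabulary, 116 regions) can be
filtered by a validation-based inclusion rule: only regions whose T1- vs
FLAIR-based volumetry agreement reaches a Spearman rho threshold
(default 0.597, inclusive) are retained before aggregation.

Image processing itself (brain extraction, segmentation, atlas warping) is
out of scope; inputs are plain TSV volume tables with an explicit unit
declaration (cm3 or mm3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CompartmentVolumes",
    "compute_icv",
    "icv_adjust",
    "filter_regions",
    "aggregate_gmv",
    "read_region_table",
    "read_correlation_table",
]

log = logging.getLogger(__name__)

RHO_THRESHOLD = 0.597
_UNIT_FACTORS = {"cm3": 1.0, "mm3": 1e-3}  # internal unit: cm3


@dataclass(frozen=True)
class CompartmentVolumes:
    """Per-subject brain compartment volumes in cm3."""

    subject_id: str
    gm: float
    wm: float
    csf: float

    def __post_init__(self):
        if min(self.gm, self.wm, self.csf) < 0:
            raise ValueError(f"{self.subject_id}: negative compartment volume")
        if self.gm + self.wm + self.csf <= 0:
            raise ValueError(f"{self.subject_id}: all compartment volumes zero")


def compute_icv(v: CompartmentVolumes) -> float:
    """Intracranial volume: GM + WM + CSF."""
    return v.gm + v.wm + v.csf


def icv_adjust(volume: float, icv: float) -> float:
    """Ratio correction: 100 * volume / ICV, in percent of intracranial volume."""
    if icv <= 0:
        raise ValueError("ICV must be positive")
    if volume < 0:
        raise ValueError("volume must be non-negative")
    if volume > icv:
        raise ValueError(f"volume {volume} exceeds ICV {icv}")
    return 100.0 * volume / icv


def _to_cm3(df: pd.DataFrame) -> pd.DataFrame:
    if "unit" not in df.columns:
        raise ValueError("region table needs a 'unit' column (cm3 or mm3)")
    bad = set(df["unit"]) - set(_UNIT_FACTORS)
    if bad:
        raise ValueError(f"unknown volume unit(s): {sorted(bad)}")
    out = df.copy()
    out["volume"] = out["volume"] * out["unit"].map(_UNIT_FACTORS)
    return out.drop(columns="unit")


def read_region_table(path) -> pd.DataFrame:
    """Read a TSV with columns subject_id, region_label, volume, unit -> cm3."""
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "region_label", "volume", "unit"}
    if not required.issubset(df.columns):
        raise ValueError(f"region table needs columns {sorted(required)}")
    if (df["volume"] < 0).any():
        raise ValueError("negative region volume")
    return _to_cm3(df)


def read_correlation_table(path) -> pd.DataFrame:
    """Read a TSV with columns region_label, rho (one row per region)."""
    df = pd.read_csv(path, sep="\t")
    if not {"region_label", "rho"}.issubset(df.columns):
        raise ValueError("correlation table needs columns region_label, rho")
    if df["region_label"].duplicated().any():
        raise ValueError("duplicate region in correlation table")
    if ((df["rho"] < -1) | (df["rho"] > 1)).any():
        raise ValueError("rho outside [-1, 1]")
    return df


def filter_regions(regions: pd.DataFrame, corr: pd.DataFrame,
                   threshold: float = RHO_THRESHOLD) -> pd.DataFrame:
    """Retain region rows whose validation rho >= threshold (inclusive).

    Every region present in ``regions`` must have a correlation row;
    a missing region is an error naming it.
    """
    rho = corr.set_index("region_label")["rho"]
    missing = sorted(set(regions["region_label"]) - set(rho.index))
    if missing:
        raise ValueError(f"region missing from correlation table: {missing[0]!r}")
    keep = regions["region_label"].map(rho) >= threshold
    return regions.loc[keep].reset_index(drop=True)


def aggregate_gmv(filtered: pd.DataFrame, icv_per_subject: dict[str, float]) -> pd.Series:
    """Per-subject ICV-adjusted GMV (%): sum of retained region volumes / ICV.

    Subjects whose retained region set is empty get 0 with a warning (the
    empty-sum convention); a subject without an ICV entry is an error.
    """
    missing = sorted(set(filtered["subject_id"]) - set(icv_per_subject))
    if missing:
        raise ValueError(f"subject without ICV: {missing[0]!r}")
    sums = filtered.groupby("subject_id")["volume"].sum()
    out = {}
    for sid, icv in icv_per_subject.items():
        total = float(sums.get(sid, 0.0))
        if total == 0.0:
            log.warning("subject %s: no retained regions, adjusted GMV set to 0", sid)
        out[sid] = icv_adjust(total, icv)
    return pd.Series(out, name="gmv_icv_pct").rename_axis("subject_id")
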