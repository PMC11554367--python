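"""Exclusion-criteria filter engine with per-criterion audit.

Encodes the screening rules used to strip records with evidence of
metabolic disease from a routine laboratory extract before indirect
reference-interval estimation: BMI outside [18.5, 25), fasting glucose
>= 100 mg/dL, A1C >= 5.7%, triglycerides >= 150 mg/dL, HDL-c below the
sex-specific minimum (50 mg/dL women / 40 mg/dL men), use of antidiabetic,
lipid-lowering or antihypertensive medication, more than two yearly exams,
or age outside 20-60 years. Thresholds are exclusion bounds: a record is
retained only when it misses every one of them (glucose 99 retained, BMI
25.0 excluded, HDL exactly at the minimum retained).

Each excluded record is attributed to the *first failing criterion* in a
configurable order, so the audit counts always sum back to the input count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ExclusionConfig", "FilterAudit", "compute_bmi",
           "apply_exclusions", "dedupe_subjects"]

DEFAULT_CRITERION_ORDER = (
    "missing_data", "age", "bmi", "glucose", "a1c", "tg", "hdl",
    "medication", "yearly_exams",
)

_MED_COLUMNS = {
    "antidiabetic": "med_antidiabetic",
    "lipid_lowering": "med_lipid_lowering",
    "antihypertensive": "med_antihypertensive",
}

_REQUIRED = ["sex", "age", "weight_kg", "height_m", "insulin_uU_mL",
             "glucose_mg_dL", "a1c_pct", "hdl_mg_dL", "tg_mg_dL",
             "yearly_exam_count"]


@dataclass
class ExclusionConfig:
    """Thresholds for the exclusion criteria (exclusion-side bounds)."""

    bmi_low: float = 18.5        # inclusive lower bound of inclusion
    bmi_high: float = 25.0       # exclusive upper bound of inclusion
    glucose_max: float = 100.0   # excluded when >=
    a1c_max: float = 5.7         # excluded when >=
    tg_max: float = 150.0        # excluded when >=
    hdl_min_f: float = 50.0      # excluded when <  (women)
    hdl_min_m: float = 40.0      # excluded when <  (men)
    excluded_medication_classes: frozenset = frozenset(_MED_COLUMNS)
    max_yearly_exams: int = 2
    age_min: float = 20.0
    age_max: float = 60.0
    criterion_order: tuple = DEFAULT_CRITERION_ORDER

    def __post_init__(self) -> None:
        if self.bmi_low >= self.bmi_high:
            raise ValueError("bmi_low must be less than bmi_high")
        for f in ("bmi_low", "bmi_high", "glucose_max", "a1c_max", "tg_max",
                  "hdl_min_f", "hdl_min_m"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        unknown = set(self.excluded_medication_classes) - set(_MED_COLUMNS)
        if unknown:
            raise ValueError(f"unknown medication classes: {sorted(unknown)}")


@dataclass
class FilterAudit:
    """Exclusion accounting: n_input = n_retained + sum of per-criterion counts."""

    n_input: int
    n_retained: int
    excluded_by_criterion: dict[str, int] = field(default_factory=dict)
    criterion_order: tuple = DEFAULT_CRITERION_ORDER

    def __post_init__(self) -> None:
        total = self.n_retained + sum(self.excluded_by_criterion.values())
        if total != self.n_input:
            raise ValueError(
                f"audit does not conserve records: {self.n_input} input vs "
                f"{self.n_retained} retained + "
                f"{sum(self.excluded_by_criterion.values())} excluded")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "excluded_by_criterion": dict(self.excluded_by_criterion),
            "criterion_order": list(self.criterion_order),
        }


def compute_bmi(weight_kg, height_m):
    """Body mass index, weight / height^2 (kg/m^2)."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    if np.any(weight_kg <= 0) or np.any(height_m <= 0):
        raise ValueError("weight and height must be positive")
    out = weight_kg / height_m ** 2
    return float(out) if out.ndim == 0 else out


def apply_exclusions(records: pd.DataFrame,
                     config: ExclusionConfig | None = None
                     ) -> tuple[pd.DataFrame, FilterAudit]:
    """Apply the exclusion criteria; return (retained records, audit).

    A record is retained iff BMI in [bmi_low, bmi_high), glucose <
    glucose_max, A1C < a1c_max, Tg < tg_max, HDL >= the sex-specific
    minimum, no excluded medication class, yearly_exam_count <=
    max_yearly_exams and age in [age_min, age_max]. Records missing a
    required field (or with an unrecognized sex code) are excluded under
    ``missing_data``.
    """
    config = config or ExclusionConfig()
    n = len(records)
    fails: dict[str, np.ndarray] = {}

    present = [c for c in _REQUIRED if c in records.columns]
    missing_cols = [c for c in _REQUIRED if c not in records.columns]
    if missing_cols:
        logger.warning("columns absent from input, all records fail "
                       "missing_data: %s", missing_cols)
        missing = np.ones(n, dtype=bool)
    else:
        missing = records[present].isna().any(axis=1).to_numpy()
    sex = records["sex"].astype(str).str.upper() if "sex" in records.columns \
        else pd.Series(["?"] * n, index=records.index)
    unknown_sex = ~sex.isin(["F", "M"]).to_numpy()
    if unknown_sex.any() and not missing_cols:
        logger.warning("%d records with unrecognized sex codes excluded "
                       "under missing_data", int(unknown_sex.sum()))
    fails["missing_data"] = missing | unknown_sex

    if not missing_cols:
        filled = records[present].fillna(0.0)
        age = filled["age"].to_numpy(dtype=float)
        bmi = np.where(
            (filled["weight_kg"] > 0) & (filled["height_m"] > 0),
            filled["weight_kg"].to_numpy(dtype=float)
            / filled["height_m"].to_numpy(dtype=float) ** 2,
            np.nan,
        )
        glucose = filled["glucose_mg_dL"].to_numpy(dtype=float)
        a1c = filled["a1c_pct"].to_numpy(dtype=float)
        tg = filled["tg_mg_dL"].to_numpy(dtype=float)
        hdl = filled["hdl_mg_dL"].to_numpy(dtype=float)
        hdl_min = np.where(sex.to_numpy() == "F", config.hdl_min_f, config.hdl_min_m)
        exams = filled["yearly_exam_count"].to_numpy(dtype=float)

        fails["age"] = (age < config.age_min) | (age > config.age_max)
        fails["bmi"] = ~((bmi >= config.bmi_low) & (bmi < config.bmi_high))
        fails["glucose"] = glucose >= config.glucose_max
        fails["a1c"] = a1c >= config.a1c_max
        fails["tg"] = tg >= config.tg_max
        fails["hdl"] = hdl < hdl_min
        med = np.zeros(n, dtype=bool)
        for cls in config.excluded_medication_classes:
            col = _MED_COLUMNS[cls]
            if col in records.columns:
                med |= records[col].fillna(False).to_numpy(dtype=bool)
        fails["medication"] = med
        fails["yearly_exams"] = exams > config.max_yearly_exams
    else:
        for crit in config.criterion_order:
            fails.setdefault(crit, np.zeros(n, dtype=bool))

    # first-failing-criterion attribution
    attributed = np.zeros(n, dtype=bool)
    counts: dict[str, int] = {}
    for crit in config.criterion_order:
        hit = fails.get(crit, np.zeros(n, dtype=bool)) & ~attributed
        counts[crit] = int(hit.sum())
        attributed |= hit

    retained = records.loc[~attributed].copy()
    audit = FilterAudit(
        n_input=n,
        n_retained=int((~attributed).sum()),
        excluded_by_criterion=counts,
        criterion_order=tuple(config.criterion_order),
    )
    return retained, audit


def dedupe_subjects(records: pd.DataFrame,
                    max_yearly_exams: int = 2) -> pd.DataFrame:
    """Collapse multi-visit subjects to one record each.

    Subjects with more than ``max_yearly_exams`` visits are removed
    entirely; for the rest, the earliest visit is kept (by ``visit_date``
    when the column exists, otherwise by input order).
    """
    if len(records) == 0 or "subject_id" not in records.columns:
        return records.copy()
    df = records.copy()
    visits = df.groupby("subject_id")["subject_id"].transform("size")
    df = df.loc[visits <= max_yearly_exams]
    if "visit_date" in df.columns:
        df = df.sort_values("visit_date", kind="stable")
    first = df.drop_duplicates(subset="subject_id", keep="first")
    return first.sort_index()
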