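"""Synthetic laboratory cohort generation with known healthy ground truth.

Emulates the structure of a routine laboratory-information-system (LIS)
extract used for indirect reference-interval estimation: a dominant healthy
subpopulation with right-skewed (lognormal) fasting insulin, contaminated by
pathological subpopulations whose insulin, glucose, BMI, A1C and lipids are
shifted towards the exclusion thresholds and whose medication flags are
enriched. Every generated record carries an ``is_healthy_truth`` label that
downstream estimation never sees; the generator also exposes the analytic
quantiles of the healthy insulin component, so recovery can be scored
exactly.

Pathological severity model
---------------------------
Each pathological member draws its insulin from one of the configured
pathological lognormal components. The member's *severity* is the concave
ramp ``s = Phi(z) ** severity_exponent`` of its insulin z-score within that
component, and every other analyte is shifted by ``multiplier ** s``
(geometric interpolation between no shift and the full-severity shift).
Severity is therefore comonotone with insulin: mildly hyperinsulinemic
members show mild comorbidity and may survive the exclusion filters, while
severely affected members essentially never do — the premise of the indirect
method, that filtering is imperfect but strongly enriching.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

__all__ = [
    "CohortSpec",
    "CohortSpecError",
    "generate_cohort",
    "true_healthy_quantiles",
    "write_cohort_csv",
    "read_cohort_csv",
    "spec_to_yaml",
    "spec_from_yaml",
]

#: Column schema of a cohort frame, one row per subject-visit.
COHORT_COLUMNS = [
    "subject_id", "sex", "age", "weight_kg", "height_m",
    "insulin_uU_mL", "glucose_mg_dL", "a1c_pct", "hdl_mg_dL", "tg_mg_dL",
    "med_antidiabetic", "med_lipid_lowering", "med_antihypertensive",
    "yearly_exam_count", "is_healthy_truth",
]

MEDICATION_CLASSES = ("antidiabetic", "lipid_lowering", "antihypertensive")


class CohortSpecError(ValueError):
    """Raised when a CohortSpec field is invalid; names the offending field."""


@dataclass
class CohortSpec:
    """Generative parameters for a synthetic LIS cohort.

    Defaults are calibrated so the healthy insulin component has median
    ~6.6 uU/mL and central 95% ~3.3-13.1 uU/mL, with ~86% women and 25%
    pathological contamination at a 2.5x insulin median shift.
    """

    n_subjects: int = 20_000
    female_fraction: float = 0.86
    healthy_fraction: float = 0.75
    # healthy fasting insulin, lognormal per sex (log uU/mL)
    insulin_healthy_logmean_f: float = math.log(6.6)
    insulin_healthy_logsd_f: float = 0.35
    insulin_healthy_logmean_m: float = math.log(6.5)
    insulin_healthy_logsd_m: float = 0.35
    # pathological insulin components: (weight, logmean, logsd)
    pathological_components: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.25, math.log(16.5), 0.45)]
    )
    glucose_healthy_mean: float = 89.0   # mg/dL
    glucose_healthy_sd: float = 5.0
    bmi_healthy_mean: float = 22.5       # kg/m^2
    bmi_healthy_sd: float = 1.8
    a1c_healthy_mean: float = 5.3        # %
    a1c_healthy_sd: float = 0.18
    tg_healthy_logmean: float = math.log(73.0)  # log mg/dL
    tg_healthy_logsd: float = 0.35
    hdl_healthy_mean_f: float = 62.0     # mg/dL
    hdl_healthy_sd_f: float = 10.0
    hdl_healthy_mean_m: float = 50.0
    hdl_healthy_sd_m: float = 9.0
    # full-severity multipliers applied to pathological members (see module
    # docstring for the severity ramp)
    pathology_shift_multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "glucose": 1.25, "bmi": 1.25, "a1c": 1.12, "tg": 2.0, "hdl": 0.8,
        }
    )
    severity_exponent: float = 0.5
    medication_prob_given_pathology: float = 0.6
    medication_prob_given_health: float = 0.05
    age_range: tuple[int, int] = (20, 60)
    insulin_glucose_rho: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self._validate()
        self._normalize_weights()

    def _validate(self) -> None:
        if self.n_subjects < 1:
            raise CohortSpecError("n_subjects must be >= 1")
        for f in ("female_fraction", "healthy_fraction",
                  "medication_prob_given_pathology",
                  "medication_prob_given_health"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise CohortSpecError(f"{f} must lie in [0, 1], got {v}")
        for f in ("insulin_healthy_logsd_f", "insulin_healthy_logsd_m"):
            if getattr(self, f) < 0:  # zero = degenerate point mass, allowed
                raise CohortSpecError(f"{f} must be non-negative")
        for f in ("glucose_healthy_sd", "bmi_healthy_sd", "a1c_healthy_sd",
                  "tg_healthy_logsd", "hdl_healthy_sd_f", "hdl_healthy_sd_m",
                  "glucose_healthy_mean", "bmi_healthy_mean",
                  "a1c_healthy_mean", "hdl_healthy_mean_f",
                  "hdl_healthy_mean_m"):
            if getattr(self, f) <= 0:
                raise CohortSpecError(f"{f} must be positive")
        for i, (w, _, ls) in enumerate(self.pathological_components):
            if not 0.0 <= w <= 1.0:
                raise CohortSpecError(
                    f"pathological_components[{i}] weight must lie in [0, 1]")
            if ls <= 0:
                raise CohortSpecError(
                    f"pathological_components[{i}] logsd must be positive")
        for name, m in self.pathology_shift_multipliers.items():
            if m <= 0:
                raise CohortSpecError(
                    f"pathology_shift_multipliers[{name!r}] must be positive")
        lo, hi = self.age_range
        if not (20 <= lo < hi <= 60):
            raise CohortSpecError(
                f"age_range must lie within [20, 60] with lo < hi, got {self.age_range}")
        if not -1.0 < self.insulin_glucose_rho < 1.0:
            raise CohortSpecError("insulin_glucose_rho must lie in (-1, 1)")

    def _normalize_weights(self) -> None:
        total = self.healthy_fraction + sum(w for w, _, _ in self.pathological_components)
        if total <= 0:
            raise CohortSpecError("healthy_fraction plus pathological weights must be positive")
        if abs(total - 1.0) > 1e-12:
            self.healthy_fraction = self.healthy_fraction / total
            self.pathological_components = [
                (w / total, lm, ls) for w, lm, ls in self.pathological_components
            ]


def _truncated_normal(rng: np.random.Generator, mean, sd, low, high, size) -> np.ndarray:
    """Draw from N(mean, sd) truncated to (low, high) by hard resampling."""
    out = rng.normal(mean, sd, size)
    for _ in range(200):
        bad = (out <= low) | (out >= high)
        if not bad.any():
            return out
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad]
                              if np.ndim(mean) else mean, sd, bad.sum())
    raise RuntimeError("truncated normal resampling did not terminate")


def _positive(rng: np.random.Generator, draw, *args) -> np.ndarray:
    """Redraw any non-positive values (hard resample on violation)."""
    out = draw(*args)
    for _ in range(200):
        bad = out <= 0
        if not bad.any():
            return out
        redrawn = draw(*args)
        out[bad] = redrawn[bad]
    raise RuntimeError("positivity resampling did not terminate")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort frame (COHORT_COLUMNS schema) from a spec.

    Deterministic for a fixed ``spec.seed``. The female record count is
    ``round(n_subjects * female_fraction)``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    n_f = int(round(n * spec.female_fraction))

    sex = np.array(["F"] * n_f + ["M"] * (n - n_f))
    rng.shuffle(sex)
    female = sex == "F"

    healthy = rng.random(n) < spec.healthy_fraction

    # insulin component assignment: 0 = healthy, 1.. = pathological components
    comp = np.zeros(n, dtype=int)
    n_path = int((~healthy).sum())
    if n_path and spec.pathological_components:
        w = np.array([c[0] for c in spec.pathological_components])
        comp[~healthy] = 1 + rng.choice(len(w), size=n_path, p=w / w.sum())
    elif n_path:
        # no pathological components declared: treat everyone as healthy
        healthy[:] = True
        comp[:] = 0

    z_insulin = rng.standard_normal(n)
    logmean = np.where(female, spec.insulin_healthy_logmean_f,
                       spec.insulin_healthy_logmean_m).astype(float)
    logsd = np.where(female, spec.insulin_healthy_logsd_f,
                     spec.insulin_healthy_logsd_m).astype(float)
    for i, (_, lm, ls) in enumerate(spec.pathological_components, start=1):
        logmean[comp == i] = lm
        logsd[comp == i] = ls
    insulin = np.exp(logmean + logsd * z_insulin)

    # severity in [0, 1]: comonotone with the insulin draw within its
    # component; zero for healthy members
    severity = np.where(
        healthy, 0.0,
        stats.norm.cdf(z_insulin) ** spec.severity_exponent,
    )
    mult = spec.pathology_shift_multipliers

    def shifted(base: np.ndarray, key: str) -> np.ndarray:
        return base * np.power(mult.get(key, 1.0), severity)

    # glucose shares a latent factor with insulin (rho) so HOMA-IR varies
    # realistically within the healthy component
    rho = spec.insulin_glucose_rho

    def _draw_glucose() -> np.ndarray:
        z_g = rho * z_insulin + math.sqrt(1 - rho * rho) * rng.standard_normal(n)
        return shifted(
            spec.glucose_healthy_mean + spec.glucose_healthy_sd * z_g, "glucose")

    glucose = _positive(rng, _draw_glucose)

    bmi = _positive(rng, lambda: shifted(
        rng.normal(spec.bmi_healthy_mean, spec.bmi_healthy_sd, n), "bmi"))
    a1c = _positive(rng, lambda: shifted(
        rng.normal(spec.a1c_healthy_mean, spec.a1c_healthy_sd, n), "a1c"))
    tg = shifted(
        np.exp(rng.normal(spec.tg_healthy_logmean, spec.tg_healthy_logsd, n)), "tg")
    hdl_mean = np.where(female, spec.hdl_healthy_mean_f, spec.hdl_healthy_mean_m)
    hdl_sd = np.where(female, spec.hdl_healthy_sd_f, spec.hdl_healthy_sd_m)
    hdl = _positive(rng, lambda: shifted(
        hdl_mean + hdl_sd * rng.standard_normal(n), "hdl"))

    height = np.where(
        female,
        _truncated_normal(rng, 1.61, 0.065, 1.2, 2.2, n),
        _truncated_normal(rng, 1.75, 0.070, 1.2, 2.2, n),
    )
    weight = bmi * height ** 2

    # medication flags: P(any excluded medication | status), then 1-3 classes
    p_any = np.where(healthy, spec.medication_prob_given_health,
                     spec.medication_prob_given_pathology)
    any_med = rng.random(n) < p_any
    n_classes = np.where(any_med, 1 + rng.binomial(2, 0.3, n), 0)
    ranks = rng.random((n, 3)).argsort(axis=1).argsort(axis=1)
    med_flags = ranks < n_classes[:, None]

    exam_probs = np.where(
        healthy[:, None],
        np.array([0.70, 0.25, 0.04, 0.01]),
        np.array([0.45, 0.30, 0.15, 0.10]),
    )
    u = rng.random(n)
    yearly_exams = 1 + (u[:, None] > exam_probs.cumsum(axis=1)).sum(axis=1)

    age = rng.integers(spec.age_range[0], spec.age_range[1] + 1, n)

    return pd.DataFrame({
        "subject_id": [f"S{i:06d}" for i in range(n)],
        "sex": sex,
        "age": age,
        "weight_kg": weight,
        "height_m": height,
        "insulin_uU_mL": insulin,
        "glucose_mg_dL": glucose,
        "a1c_pct": a1c,
        "hdl_mg_dL": hdl,
        "tg_mg_dL": tg,
        "med_antidiabetic": med_flags[:, 0],
        "med_lipid_lowering": med_flags[:, 1],
        "med_antihypertensive": med_flags[:, 2],
        "yearly_exam_count": yearly_exams,
        "is_healthy_truth": healthy,
    })


def true_healthy_quantiles(spec: CohortSpec, sex: str, probs) -> np.ndarray:
    """Analytic quantiles (uU/mL) of the healthy insulin component.

    For a single sex these are the closed-form lognormal quantiles
    ``exp(logmean + z_p * logsd)``; for ``sex="all"`` the female/male
    lognormal mixture CDF is inverted numerically.
    """
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("probs must lie strictly inside (0, 1)")
    params = {
        "F": (spec.insulin_healthy_logmean_f, spec.insulin_healthy_logsd_f),
        "M": (spec.insulin_healthy_logmean_m, spec.insulin_healthy_logsd_m),
    }
    if sex in params:
        lm, ls = params[sex]
        return np.exp(lm + stats.norm.ppf(probs) * ls)
    if sex != "all":
        raise ValueError(f"sex must be 'F', 'M' or 'all', got {sex!r}")

    w_f = spec.female_fraction
    (lm_f, ls_f), (lm_m, ls_m) = params["F"], params["M"]
    if (lm_f, ls_f) == (lm_m, ls_m):
        return np.exp(lm_f + stats.norm.ppf(probs) * ls_f)

    def cdf(x: float) -> float:
        return (w_f * stats.norm.cdf((math.log(x) - lm_f) / ls_f)
                + (1 - w_f) * stats.norm.cdf((math.log(x) - lm_m) / ls_m))

    out = np.empty_like(probs)
    for i, p in enumerate(probs):
        zp = stats.norm.ppf(p)
        lo = 0.5 * min(math.exp(lm_f + zp * ls_f), math.exp(lm_m + zp * ls_m))
        hi = 2.0 * max(math.exp(lm_f + zp * ls_f), math.exp(lm_m + zp * ls_m))
        out[i] = optimize.brentq(lambda x: cdf(x) - p, lo, hi, xtol=1e-12)
    return out


# ---------------------------------------------------------------------------
# serialization

def write_cohort_csv(records: pd.DataFrame, path, spec: CohortSpec | None = None) -> None:
    """Write a cohort CSV; if a spec is given, record seed/spec provenance
    in an adjacent ``<path>.provenance.json``.

    Floats are written with 17 significant digits so the CSV round-trips
    bit-exactly.
    """
    records.to_csv(path, index=False, float_format="%.17g")
    if spec is not None:
        prov = {"seed": spec.seed, "spec": _spec_dict(spec)}
        with open(f"{path}.provenance.json", "w") as fh:
            json.dump(prov, fh, indent=2)


def load_example_cohort() -> pd.DataFrame:
    """The packaged 12-record worked-example cohort (synthetic, hand-built).

    Exactly five records (P01-P05) satisfy the default exclusion criteria,
    including boundary cases retained by a hair (BMI 24.9, glucose 99,
    A1C 5.6, Tg 149, HDL-c exactly at the sex minimum, age 60). The seven
    F-records each fail exactly one criterion: BMI 25.0, BMI 17.6, glucose
    100, A1C 5.7, Tg 150, HDL-c 49 in a woman, and antihypertensive use.
    """
    from importlib.resources import files

    with files("refrange.data").joinpath("example_cohort.csv").open() as fh:
        return read_cohort_csv(fh)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("med_antidiabetic", "med_lipid_lowering", "med_antihypertensive"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    if "is_healthy_truth" in df.columns:
        df["is_healthy_truth"] = df["is_healthy_truth"].astype(bool)
    return df


def _spec_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["pathological_components"] = [list(c) for c in spec.pathological_components]
    d["age_range"] = list(spec.age_range)
    return d


def spec_to_yaml(spec: CohortSpec, path=None) -> str:
    text = yaml.safe_dump(_spec_dict(spec), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def spec_from_yaml(source) -> CohortSpec:
    """Load a CohortSpec from YAML text or a file path."""
    try:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    except (OSError, TypeError):
        data = yaml.safe_load(source)
    data["pathological_components"] = [
        tuple(c) for c in data.get("pathological_components", [])
    ]
    data["age_range"] = tuple(data.get("age_range", (20, 60)))
    return CohortSpec(**data)
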