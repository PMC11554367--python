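"""End-to-end study orchestration and report rendering.

``run_study`` replays the whole indirect reference-interval workflow on a
cohort (synthetic spec, DataFrame, or CSV path): de-duplication, exclusion
filtering, HOMA-IR computation, per-sex descriptive summaries with
Mann-Whitney comparisons, age-decade strata, reference-interval estimation
for fasting insulin and HOMA-IR in women, men and the overall population,
and a Harris-Boyd sex-partitioning decision per analyte. The resulting
``StudyReport`` holds plain JSON-serializable data plus full provenance
(resolved configuration and seeds), so any number in the report can be
recomputed from the JSON alone.
"""

from __future__ import annotations

import dataclasses
import io
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .analytes import UnitConvention, WHO, add_homa_column, convert, round_for_display
from .cohort import CohortSpec, generate_cohort, read_cohort_csv, _spec_dict
from .estimate import RIConfig, DEFAULT_CONFIG, run_indirect_ri
from .filters import ExclusionConfig, apply_exclusions, dedupe_subjects
from .partition import harris_boyd_transformed, mann_whitney

logger = logging.getLogger(__name__)

__all__ = ["StudyReport", "run_study", "render_report"]

SCHEMA_VERSION = 1

AGE_BANDS = ((20, 29), (30, 39), (40, 49), (50, 60))

# analyte -> (column, convert-key or None)
_SUMMARY_ANALYTES = {
    "age": ("age", None),
    "bmi": ("bmi", None),
    "insulin": ("insulin_uU_mL", "insulin"),
    "glucose": ("glucose_mg_dL", "glucose"),
    "hdl": ("hdl_mg_dL", "hdl"),
    "a1c": ("a1c_pct", None),
    "tg": ("tg_mg_dL", "tg"),
    "homa_ir": ("homa_ir", None),
}

_RI_ANALYTES = {"insulin": "insulin_uU_mL", "homa_ir": "homa_ir"}
_GROUPS = ("F", "M", "all")


@dataclass
class StudyReport:
    """Full study output; every field is plain JSON-serializable data."""

    cohort_summary: dict
    age_strata: list
    ri_table: dict
    partition: dict
    audit: dict
    provenance: dict
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyReport":
        return cls(**d)


def _summary_for(df: pd.DataFrame, convention: UnitConvention) -> dict:
    out = {}
    for name, (col, conv_key) in _SUMMARY_ANALYTES.items():
        x = df[col]
        entry = {"median": float(x.median()), "min": float(x.min()),
                 "max": float(x.max())}
        if conv_key is not None:
            for k in ("median", "min", "max"):
                entry[k + "_si"] = float(
                    convert(entry[k], conv_key, "to_si", convention))
        out[name] = entry
    return out


def run_study(cohort_source, ri_config: RIConfig = DEFAULT_CONFIG,
              exclusion_config: ExclusionConfig | None = None,
              convention: UnitConvention = WHO, seed: int = 0) -> StudyReport:
    """Run the full indirect reference-interval study on a cohort.

    Parameters
    ----------
    cohort_source : CohortSpec, pandas.DataFrame, or CSV path
        The input cohort. A spec is generated with its own seed.
    seed : int
        Drives the six reference-interval estimations (EM restarts and
        bootstraps); the report is deterministic for a fixed seed.
    """
    exclusion_config = exclusion_config or ExclusionConfig()
    if isinstance(cohort_source, CohortSpec):
        records = generate_cohort(cohort_source)
        source_desc = {"type": "synthetic", "spec": _spec_dict(cohort_source)}
    elif isinstance(cohort_source, pd.DataFrame):
        records = cohort_source
        source_desc = {"type": "dataframe", "n": int(len(cohort_source))}
    else:
        records = read_cohort_csv(cohort_source)
        source_desc = {"type": "csv", "path": str(cohort_source)}

    records = dedupe_subjects(records, exclusion_config.max_yearly_exams)
    retained, audit = apply_exclusions(records, exclusion_config)
    logger.info("filter: %d of %d records retained", audit.n_retained, audit.n_input)
    retained = add_homa_column(retained, convention)
    retained = retained.assign(
        bmi=retained["weight_kg"] / retained["height_m"] ** 2)

    female = retained[retained["sex"] == "F"]
    male = retained[retained["sex"] == "M"]

    cohort_summary = {
        "n": {"F": int(len(female)), "M": int(len(male)),
              "all": int(len(retained))},
        "by_sex": {"F": _summary_for(female, convention),
                   "M": _summary_for(male, convention)},
        "p_values": {},
        "convention": convention.name,
    }
    for name, (col, _) in _SUMMARY_ANALYTES.items():
        if len(female) and len(male):
            _, p = mann_whitney(female[col], male[col])
            cohort_summary["p_values"][name] = float(p)

    age_strata = []
    for lo, hi in AGE_BANDS:
        band = retained[(retained["age"] >= lo) & (retained["age"] <= hi)]
        row = {"band": f"{lo}-{hi}", "n": int(len(band))}
        for name in ("bmi", "insulin", "glucose", "tg", "hdl"):
            col, conv_key = _SUMMARY_ANALYTES[name]
            med = float(band[col].median()) if len(band) else float("nan")
            row[name + "_median"] = med
            if conv_key is not None and len(band):
                row[name + "_median_si"] = float(
                    convert(med, conv_key, "to_si", convention))
        age_strata.append(row)

    # six independent estimations: 2 analytes x (F, M, all)
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(_RI_ANALYTES) * len(_GROUPS)) % (2 ** 31)
    ri_table: dict = {}
    i = 0
    for analyte, col in _RI_ANALYTES.items():
        ri_table[analyte] = {}
        for group in _GROUPS:
            sub = retained if group == "all" else retained[retained["sex"] == group]
            est = run_indirect_ri(sub[col].to_numpy(), config=ri_config,
                                  seed=int(child_seeds[i]))
            ri_table[analyte][group] = est.to_dict()
            i += 1

    partition = {}
    for analyte, col in _RI_ANALYTES.items():
        dec = harris_boyd_transformed(female[col], male[col], config=ri_config)
        partition[analyte] = dec.to_dict()

    provenance = {
        "package_version": __version__,
        "seed": int(seed),
        "source": source_desc,
        "ri_config": dataclasses.asdict(ri_config),
        "exclusion_config": {
            **{k: v for k, v in dataclasses.asdict(exclusion_config).items()
               if k not in ("excluded_medication_classes", "criterion_order")},
            "excluded_medication_classes":
                sorted(exclusion_config.excluded_medication_classes),
            "criterion_order": list(exclusion_config.criterion_order),
        },
        "convention": dataclasses.asdict(convention),
    }
    _jsonify(provenance)
    return StudyReport(
        cohort_summary=cohort_summary, age_strata=age_strata,
        ri_table=ri_table, partition=partition, audit=audit.to_dict(),
        provenance=provenance,
    )


def _jsonify(obj):
    """Coerce tuples/numpy scalars in-place-ish so json round-trips exactly."""
    if isinstance(obj, dict):
        for k, v in obj.items():
            if isinstance(v, tuple):
                obj[k] = list(v)
            if isinstance(v, (np.integer,)):
                obj[k] = int(v)
            if isinstance(v, (np.floating,)):
                obj[k] = float(v)
            if isinstance(v, (dict, list)):
                _jsonify(v)
    elif isinstance(obj, list):
        for i, v in enumerate(obj):
            if isinstance(v, tuple):
                obj[i] = list(v)
            if isinstance(v, (np.integer,)):
                obj[i] = int(v)
            if isinstance(v, (np.floating,)):
                obj[i] = float(v)
            if isinstance(v, (dict, list)):
                _jsonify(v)


def _fmt_pair(value: float, si: float | None, kind: str = "analyte") -> str:
    if si is None:
        return f"{round_for_display(value, kind)}"
    return f"{round_for_display(value, kind)}/{round_for_display(si)}"


def _markdown(report: StudyReport) -> str:
    buf = io.StringIO()
    s = report.cohort_summary
    print("# Indirect reference-interval study report\n", file=buf)
    print(f"Retained cohort: {s['n']['all']} subjects "
          f"({s['n']['F']} women, {s['n']['M']} men); "
          f"unit convention: {s['convention']}\n", file=buf)
    print("## Cohort characteristics by sex\n", file=buf)
    print("| Characteristic | Women | Men | p |", file=buf)
    print("|---|---|---|---|", file=buf)
    for name in _SUMMARY_ANALYTES:
        cells = []
        for sex in ("F", "M"):
            e = report.cohort_summary["by_sex"][sex][name]
            kind = "homa" if name == "homa_ir" else "analyte"
            med = _fmt_pair(e["median"], e.get("median_si"), kind)
            rng = (f"{_fmt_pair(e['min'], e.get('min_si'), kind)}-"
                   f"{_fmt_pair(e['max'], e.get('max_si'), kind)}")
            cells.append(f"{med} ({rng})")
        p = report.cohort_summary["p_values"].get(name, float("nan"))
        print(f"| {name} | {cells[0]} | {cells[1]} | {p:.3g} |", file=buf)
    print("\n## Medians by age band\n", file=buf)
    print("| Age, years | n | BMI | Insulin | Glucose | Tgs | HDL-c |", file=buf)
    print("|---|---|---|---|---|---|---|", file=buf)
    for row in report.age_strata:
        print(f"| {row['band']} | {row['n']} | {row['bmi_median']:.2f} | "
              f"{_fmt_pair(row['insulin_median'], row.get('insulin_median_si'))} | "
              f"{_fmt_pair(row['glucose_median'], row.get('glucose_median_si'))} | "
              f"{_fmt_pair(row['tg_median'], row.get('tg_median_si'))} | "
              f"{_fmt_pair(row['hdl_median'], row.get('hdl_median_si'))} |",
              file=buf)
    print("\n## Reference intervals (central 95%, 90% CIs)\n", file=buf)
    print("| Analyte | Group | n | RI | Lower 90% CI | Upper 90% CI |", file=buf)
    print("|---|---|---|---|---|---|", file=buf)
    for analyte, groups in report.ri_table.items():
        kind = "homa" if analyte == "homa_ir" else "analyte"
        for group, est in groups.items():
            ri = (f"{round_for_display(est['lower'], kind)}-"
                  f"{round_for_display(est['upper'], kind)}")
            lci = "-".join(str(round_for_display(v, kind)) for v in est["lower_ci"])
            uci = "-".join(str(round_for_display(v, kind)) for v in est["upper_ci"])
            print(f"| {analyte} | {group} | {est['n_in_window']} | {ri} | "
                  f"{lci} | {uci} |", file=buf)
    print("\n## Sex partitioning (Harris-Boyd)\n", file=buf)
    for analyte, dec in report.partition.items():
        verdict = "required" if dec["partition_required"] else "not required"
        print(f"- {analyte}: partition {verdict} "
              f"(z = {dec['z']:.3f} vs z* = {dec['z_star']:.3f}, "
              f"SD ratio = {dec['sd_ratio']:.3f})", file=buf)
    return buf.getvalue()


def _csv(report: StudyReport) -> str:
    rows = []
    for analyte, groups in report.ri_table.items():
        for group, est in groups.items():
            rows.append({
                "analyte": analyte, "group": group,
                "n_input": est["n_input"],
                "n_in_window": est["n_in_window"],
                "ri_lower": est["lower"], "ri_upper": est["upper"],
                "lower_ci_lo": est["lower_ci"][0],
                "lower_ci_hi": est["lower_ci"][1],
                "upper_ci_lo": est["upper_ci"][0],
                "upper_ci_hi": est["upper_ci"][1],
            })
    return pd.DataFrame(rows).to_csv(index=False)


def render_report(report: StudyReport, format: str = "json") -> str:
    """Render a StudyReport as ``json`` (lossless), ``markdown`` or ``csv``."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    if format == "markdown":
        return _markdown(report)
    if format == "csv":
        return _csv(report)
    raise ValueError(f"unknown format {format!r}; expected json, markdown or csv")
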