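"""HOMA-IR computation and analyte unit conversions.

The homeostasis model assessment of insulin resistance (HOMA-IR) is

    HOMA-IR = fasting glucose [mmol/L] * fasting insulin [uU/mL] / 22.5

Two insulin unit conventions circulate in the clinical literature:

* the WHO/ADA factor, 1 uU/mL = 6.00 pmol/L, and
* a legacy reciprocal convention in which pmol/L values are *multiplied by
  0.166* to obtain uU/mL, i.e. 1 uU/mL = 1/0.166 = 6.024 pmol/L.

The two differ by a fixed ratio of 6.00 * 0.166 = 0.996, which is why tables
converted with one convention cannot be reproduced exactly with the other.
Both are exposed; ``WHO`` is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

HOMA_IR_DENOMINATOR = 22.5


@dataclass(frozen=True)
class UnitConvention:
    """Multiplicative factors mapping conventional units to SI units."""

    name: str = "who"
    insulin_uU_to_pmol_factor: float = 6.00
    glucose_mg_per_mmol: float = 18.02
    tg_mg_per_mmol: float = 88.5
    hdl_mg_per_mmol: float = 38.67

    def __post_init__(self) -> None:
        for f in ("insulin_uU_to_pmol_factor", "glucose_mg_per_mmol",
                  "tg_mg_per_mmol", "hdl_mg_per_mmol"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


#: WHO/ADA recommendation: 1 uU/mL = 6.00 pmol/L.
WHO = UnitConvention(name="who", insulin_uU_to_pmol_factor=6.00)

#: Legacy reciprocal convention: pmol/L * 0.166 = uU/mL.
LEGACY_RECIPROCAL = UnitConvention(
    name="legacy_reciprocal", insulin_uU_to_pmol_factor=1.0 / 0.166
)

# to_si multiplies by the factor for insulin (uU/mL -> pmol/L) and divides
# for the mg/dL analytes (mg/dL -> mmol/L).
_SI_FACTORS = {
    "insulin": ("insulin_uU_to_pmol_factor", "mul"),
    "glucose": ("glucose_mg_per_mmol", "div"),
    "tg": ("tg_mg_per_mmol", "div"),
    "hdl": ("hdl_mg_per_mmol", "div"),
}


def homa_ir(glucose_mmol: float, insulin_uU_mL: float) -> float:
    """HOMA-IR index from fasting glucose (mmol/L) and insulin (uU/mL).

    Raises
    ------
    ValueError
        If either input is not strictly positive.
    """
    if glucose_mmol <= 0:
        raise ValueError(f"glucose must be positive, got {glucose_mmol}")
    if insulin_uU_mL <= 0:
        raise ValueError(f"insulin must be positive, got {insulin_uU_mL}")
    return glucose_mmol * insulin_uU_mL / HOMA_IR_DENOMINATOR


def convert(value, analyte: str, direction: str,
            convention: UnitConvention = WHO):
    """Convert an analyte amount between conventional and SI units.

    Parameters
    ----------
    value : float or array-like, >= 0
        Amount in the source unit (conventional for ``to_si``, SI for
        ``from_si``).
    analyte : {"insulin", "glucose", "tg", "hdl"}
    direction : {"to_si", "from_si"}
        Conventional units are uU/mL (insulin) and mg/dL (glucose, Tg,
        HDL-c); SI units are pmol/L and mmol/L respectively.
    convention : UnitConvention
        The factor set to use; default WHO.
    """
    if analyte not in _SI_FACTORS:
        raise ValueError(
            f"unknown analyte {analyte!r}; expected one of {sorted(_SI_FACTORS)}"
        )
    if direction not in ("to_si", "from_si"):
        raise ValueError(f"direction must be 'to_si' or 'from_si', got {direction!r}")
    attr, mode = _SI_FACTORS[analyte]
    factor = getattr(convention, attr)
    if (mode == "mul") == (direction == "to_si"):
        return value * factor
    return value / factor


def round_for_display(value: float, kind: str = "analyte") -> float:
    """Display rounding: 1 decimal for converted analytes, 2 for HOMA-IR."""
    return round(value, 2 if kind == "homa" else 1)


def add_homa_column(records: pd.DataFrame,
                    convention: UnitConvention = WHO) -> pd.DataFrame:
    """Return a copy of the cohort with a ``homa_ir`` column appended.

    Glucose is stored in mg/dL and is converted to mmol/L (via the
    convention's glucose factor) before applying the HOMA-IR formula.
    Input row order is preserved.
    """
    out = records.copy()
    if len(out) == 0:
        out["homa_ir"] = pd.Series(dtype=float)
        return out
    glucose = out["glucose_mg_dL"]
    insulin = out["insulin_uU_mL"]
    bad = (glucose <= 0) | (insulin <= 0) | glucose.isna() | insulin.isna()
    if bad.any():
        offender = out.loc[bad].iloc[0]
        raise ValueError(
            "non-positive glucose/insulin for subject "
            f"{offender.get('subject_id', '<unknown>')!r}"
        )
    glucose_mmol = convert(glucose, "glucose", "to_si", convention)
    out["homa_ir"] = glucose_mmol * insulin / HOMA_IR_DENOMINATOR
    return out
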