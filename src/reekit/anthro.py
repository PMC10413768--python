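"""BMI, LMS-based BMI-for-age z-scores, and weight-status classification.

The LMS (lambda-mu-sigma) transform standardizes a measurement against an
age- and sex-specific growth reference:

    z = ((x/M)**L - 1) / (L*S)   if L != 0
    z = ln(x/M) / S              if L == 0

No reference table is bundled as authoritative data; any LMS CSV with
columns ``sex,age_unit,age,L,M,S`` can be loaded, and
:func:`synthetic_lms_table` provides a smooth made-up reference so tests and
demos run without downloads.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equations import Sex
from .exceptions import ConfigurationError, CoverageError, DomainError

__all__ = [
    "BmiGroup",
    "LMSRow",
    "LMSTable",
    "bmi",
    "lms_zscore",
    "lms_inverse",
    "classify_bmi_group",
    "synthetic_lms_table",
]


class BmiGroup(str, enum.Enum):
    thin = "thin"
    normal = "normal"
    overweight = "overweight"
    obese = "obese"


#: |L| below this uses the L=0 (log) form of the Box-Cox transform.
_L_TINY = 1e-8


def bmi(weight: float, height: float) -> float:
    """Body mass index from weight (kg) and height (cm)."""
    if not weight > 0:
        raise DomainError(f"weight must be > 0, got {weight}")
    if not height > 0:
        raise DomainError(f"height must be > 0, got {height}")
    return weight / (height / 100.0) ** 2


@dataclass(frozen=True)
class LMSRow:
    """Box-Cox parameters of a growth reference at one sex/age."""

    sex: Sex
    age: float  # decimal years
    L: float
    M: float
    S: float

    def __post_init__(self):
        if not self.M > 0 or not self.S > 0:
            raise ConfigurationError(
                f"LMS row at age {self.age}: M and S must be > 0"
            )


def lms_zscore(x: float, row: LMSRow) -> float:
    """Standard-deviation score of measurement ``x`` under an LMS row."""
    if not x > 0:
        raise DomainError(f"measurement must be > 0, got {x}")
    if abs(row.L) < _L_TINY:  # analytic L -> 0 limit
        return math.log(x / row.M) / row.S
    # expm1 keeps the Box-Cox form stable for small L
    return math.expm1(row.L * math.log(x / row.M)) / (row.L * row.S)


def lms_inverse(z: float, row: LMSRow) -> float:
    """Measurement corresponding to a z-score (inverse of :func:`lms_zscore`)."""
    if abs(row.L) < _L_TINY:
        return row.M * math.exp(row.S * z)
    return row.M * math.exp(math.log1p(row.L * row.S * z) / row.L)


def classify_bmi_group(z: float) -> BmiGroup:
    """WHO-2007 convention: obese > +2 SD, overweight > +1 SD, thin < -2 SD.

    Boundary values go to the lower category (z == 1 is normal, z == 2 is
    overweight).
    """
    if not math.isfinite(z):
        raise DomainError(f"z-score must be finite, got {z}")
    if z > 2:
        return BmiGroup.obese
    if z > 1:
        return BmiGroup.overweight
    if z >= -2:
        return BmiGroup.normal
    return BmiGroup.thin


class LMSTable:
    """A sex-stratified LMS reference with linear age interpolation.

    Parameters are interpolated linearly in age between bracketing rows; ages
    outside a sex's coverage raise :class:`CoverageError` (no extrapolation).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"sex", "age_years", "L", "M", "S"}
        missing = required - set(frame.columns)
        if missing:
            raise ConfigurationError(f"LMS table missing columns: {sorted(missing)}")
        frame = frame.copy()
        frame["sex"] = frame["sex"].map(lambda s: Sex(s).value)
        frame = frame.sort_values(["sex", "age_years"]).reset_index(drop=True)
        for sex, grp in frame.groupby("sex"):
            if grp["age_years"].duplicated().any():
                raise ConfigurationError(f"duplicate ages in LMS table for {sex}")
            if (grp["M"] <= 0).any() or (grp["S"] <= 0).any():
                raise ConfigurationError("LMS table requires M > 0 and S > 0")
        self.frame = frame

    @classmethod
    def from_csv(cls, path) -> "LMSTable":
        """Read an LMS CSV with columns sex,age_unit,age,L,M,S."""
        raw = pd.read_csv(path, comment="#")
        required = {"sex", "age_unit", "age", "L", "M", "S"}
        missing = required - set(raw.columns)
        if missing:
            raise ConfigurationError(f"LMS CSV missing columns: {sorted(missing)}")
        bad_units = set(raw["age_unit"]) - {"months", "years"}
        if bad_units:
            raise ConfigurationError(f"unknown age_unit values: {sorted(bad_units)}")
        raw = raw.copy()
        raw["age_years"] = np.where(
            raw["age_unit"] == "months", raw["age"] / 12.0, raw["age"]
        )
        return cls(raw[["sex", "age_years", "L", "M", "S"]])

    def coverage(self, sex: Sex) -> tuple[float, float]:
        grp = self.frame[self.frame["sex"] == Sex(sex).value]
        if grp.empty:
            raise CoverageError(f"no LMS rows for sex={Sex(sex).value}")
        return float(grp["age_years"].min()), float(grp["age_years"].max())

    def lookup(self, sex: Sex, age: float) -> LMSRow:
        """LMS parameters at (sex, age), linearly interpolated."""
        sex = Sex(sex)
        grp = self.frame[self.frame["sex"] == sex.value]
        lo, hi = self.coverage(sex)
        if not (lo <= age <= hi):
            raise CoverageError(
                f"age {age} outside LMS coverage [{lo}, {hi}] for {sex.value}"
            )
        ages = grp["age_years"].to_numpy()
        L = float(np.interp(age, ages, grp["L"].to_numpy()))
        M = float(np.interp(age, ages, grp["M"].to_numpy()))
        S = float(np.interp(age, ages, grp["S"].to_numpy()))
        return LMSRow(sex=sex, age=age, L=L, M=M, S=S)

    def bmi_zscore(self, sex: Sex, age: float, bmi_value: float) -> float:
        return lms_zscore(bmi_value, self.lookup(sex, age))


def synthetic_lms_table(age_min: float = 5.0, age_max: float = 19.0) -> LMSTable:
    """A smooth, entirely synthetic BMI-for-age reference for tests/demos.

    Curves are made up but shaped plausibly: median BMI rising with age,
    slightly higher for males in adolescence, mild skewness (L < 0) and a
    gently increasing coefficient of variation.  Not a real growth standard.
    """
    ages = np.arange(age_min, age_max + 0.5, 0.5)
    rows = []
    for sex, m_shift in ((Sex.male, 0.2), (Sex.female, 0.0)):
        for a in ages:
            t = (a - age_min) / (age_max - age_min)
            rows.append(
                {
                    "sex": sex.value,
                    "age_years": float(a),
                    "L": -1.6 + 0.6 * t,
                    "M": 15.2 + 6.0 * t**1.2 + m_shift * t,
                    "S": 0.085 + 0.035 * t,
                }
            )
    return LMSTable(pd.DataFrame(rows))
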