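"""Validation statistics: accuracy %, bias %, RMSE and Bland-Altman agreement.

Conventions (all exposed in :class:`reekit.config.Settings`):

* an "accurate" prediction falls within 90-110% of the measured value,
  boundary inclusive;
* bias % is the mean of per-subject percentage differences with the measured
  value as denominator;
* RMSE uses the plain 1/n mean of squared differences;
* Bland-Altman limits of agreement are mean difference +/- 2 * SD of the
  differences (multiplier exactly 2, sample SD with the n-1 denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_SETTINGS, Settings
from .equations import Cohort
from .exceptions import DomainError

__all__ = [
    "ValidationSummary",
    "BlandAltmanResult",
    "accurate_prediction_rate",
    "bias_percent",
    "rmse",
    "bland_altman",
    "stratified_validation",
    "BMI_STRATA",
    "SEX_STRATA",
]

BMI_STRATA = ("overall", "normal", "overweight", "obese")
SEX_STRATA = ("both", "male", "female")


def _as_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise DomainError("empty pair list")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("pairs must be (predicted, measured) tuples")
    return arr[:, 0], arr[:, 1]


def accurate_prediction_rate(
    pairs, settings: Settings = DEFAULT_SETTINGS
) -> float:
    """% of subjects whose prediction is within 90-110% of the measurement."""
    predicted, measured = _as_pairs(pairs)
    if (measured <= 0).any():
        raise DomainError("measured values must be > 0")
    ratio = predicted / measured
    if settings.accuracy_inclusive:
        ok = (ratio >= 0.90) & (ratio <= 1.10)
    else:
        ok = (ratio > 0.90) & (ratio < 1.10)
    return 100.0 * float(ok.mean())


def bias_percent(pairs) -> float:
    """Mean per-subject percentage difference, 100*(predicted-measured)/measured."""
    predicted, measured = _as_pairs(pairs)
    if (measured <= 0).any():
        raise DomainError("measured values must be > 0")
    return float(np.mean(100.0 * (predicted - measured) / measured))


def rmse(pairs) -> float:
    """Root mean squared prediction error in kcal/d (1/n denominator)."""
    predicted, measured = _as_pairs(pairs)
    return float(np.sqrt(np.mean((predicted - measured) ** 2)))


def mean_difference(pairs) -> float:
    predicted, measured = _as_pairs(pairs)
    return float(np.mean(predicted - measured))


@dataclass(frozen=True)
class BlandAltmanResult:
    """Per-subject agreement points plus limits of agreement."""

    means: np.ndarray  # (predicted + measured) / 2 per subject
    differences: np.ndarray  # predicted - measured per subject
    mean_diff: float
    sd_diff: float
    lower_loa: float
    upper_loa: float
    outlier_count: int
    multiplier: float

    def to_points_frame(self, ids=None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"mean_kcal_d": self.means, "diff_kcal_d": self.differences}
        )
        if ids is not None:
            frame.insert(0, "id", list(ids))
        return frame

    def to_limits_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "lower_loa": self.lower_loa,
            "upper_loa": self.upper_loa,
            "outlier_count": self.outlier_count,
            "multiplier": self.multiplier,
            "n": int(len(self.differences)),
        }


def bland_altman(pairs, settings: Settings = DEFAULT_SETTINGS) -> BlandAltmanResult:
    """Bland-Altman agreement analysis of predicted vs measured values."""
    predicted, measured = _as_pairs(pairs)
    if len(predicted) < 2:
        raise DomainError("Bland-Altman analysis needs at least 2 pairs")
    differences = predicted - measured
    means = (predicted + measured) / 2.0
    mean_diff = float(differences.mean())
    sd_diff = float(differences.std(ddof=1))
    m = settings.ba_multiplier
    lower, upper = mean_diff - m * sd_diff, mean_diff + m * sd_diff
    outliers = int(np.sum(np.abs(differences - mean_diff) > m * sd_diff))
    return BlandAltmanResult(
        means=means,
        differences=differences,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        lower_loa=lower,
        upper_loa=upper,
        outlier_count=outliers,
        multiplier=m,
    )


@dataclass(frozen=True)
class ValidationSummary:
    """Validation statistics for one (equation, stratum) cell."""

    equation_id: str
    bmi_stratum: str
    sex_stratum: str
    n: int
    n_inapplicable: int
    mean_difference: float  # kcal/d, predicted - measured; NaN when n == 0
    accurate_pct: float
    bias_pct: float
    rmse: float


def _summary_for(
    equation_id: str,
    bmi_stratum: str,
    sex_stratum: str,
    sub: pd.DataFrame,
    settings: Settings,
) -> ValidationSummary:
    applicable = sub[sub["predicted_ree_kcal_d"].notna()]
    n = len(applicable)
    n_inapplicable = len(sub) - n
    if n == 0:
        nan = float("nan")
        return ValidationSummary(
            equation_id, bmi_stratum, sex_stratum, 0, n_inapplicable, nan, nan, nan, nan
        )
    pairs = applicable[["predicted_ree_kcal_d", "measured_ree_kcal_d"]].to_numpy()
    return ValidationSummary(
        equation_id=equation_id,
        bmi_stratum=bmi_stratum,
        sex_stratum=sex_stratum,
        n=n,
        n_inapplicable=n_inapplicable,
        mean_difference=mean_difference(pairs),
        accurate_pct=accurate_prediction_rate(pairs, settings),
        bias_pct=bias_percent(pairs),
        rmse=rmse(pairs),
    )


def stratified_validation(
    cohort: Cohort,
    predictions: pd.DataFrame,
    bmi_strata=BMI_STRATA,
    sex_strata=SEX_STRATA,
    settings: Settings = DEFAULT_SETTINGS,
) -> pd.DataFrame:
    """One :class:`ValidationSummary` row per equation x BMI stratum x sex stratum.

    Every statistic is recomputed from the raw (predicted, measured) pairs of
    the stratum — never by aggregating sub-stratum aggregates.  Empty strata
    are emitted with NaN statistics, never dropped.
    """
    cohort_frame = cohort.to_frame()
    missing_ree = cohort_frame["measured_ree_kcal_d"].isna()
    if missing_ree.any():
        raise DomainError(
            f"{int(missing_ree.sum())} subject(s) lack measured REE"
        )
    missing_group = cohort_frame["bmi_group"].isna()
    if missing_group.any():
        raise DomainError(
            f"{int(missing_group.sum())} subject(s) lack a BMI group"
        )
    merged = predictions.merge(
        cohort_frame[["id", "sex", "bmi_group", "measured_ree_kcal_d"]],
        on="id",
        how="left",
        validate="many_to_one",
    )
    summaries = []
    for eq_id, eq_sub in merged.groupby("equation_id", sort=False):
        for bmi_stratum in bmi_strata:
            sub_b = (
                eq_sub
                if bmi_stratum == "overall"
                else eq_sub[eq_sub["bmi_group"] == bmi_stratum]
            )
            for sex_stratum in sex_strata:
                sub = (
                    sub_b
                    if sex_stratum == "both"
                    else sub_b[sub_b["sex"] == sex_stratum]
                )
                summaries.append(
                    _summary_for(eq_id, bmi_stratum, sex_stratum, sub, settings)
                )
    return pd.DataFrame([s.__dict__ for s in summaries])


def presentation_table(validation: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """One-decimal presentation rounding of a validation table."""
    out = validation.copy()
    for col in ("mean_difference", "accurate_pct", "bias_pct", "rmse"):
        out[col] = out[col].round(decimals)
    return out
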