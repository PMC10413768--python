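"""Pediatric REE prediction equations and their evaluation.

This module encodes the 14 resting-energy-expenditure prediction equations
used by the pipeline: 13 literature equations (WHO, Schofield, IOM, Kim,
Henry, Molnar, two Muller forms, Derumeaux-Burel, Schmelzle, Tverskaya, two
Lazzer forms) plus the FFM-based equation developed by the modeling module.
Coefficients are stored exactly as published, in each equation's native
energy unit, with each equation's own sex-coding convention; evaluation
normalizes everything to kcal/day.

Two published quirks are kept deliberately (see the package README):
Muller's equations are coded male=0/female=1 here even though the original
2004 publication codes male=1, and Derumeaux-Burel is a single sex-free formula
although the original is sex-specific.  Both reflect the tabulation this
registry reproduces.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import DEFAULT_SETTINGS, Settings
from .exceptions import (
    ConfigurationError,
    DispatchError,
    DomainError,
    InapplicableError,
)

__all__ = [
    "Sex",
    "EnergyUnit",
    "Subject",
    "Cohort",
    "Variant",
    "EquationSpec",
    "Prediction",
    "convert_energy",
    "predict_ree",
    "predict_all",
    "equation_registry",
    "get_equation",
    "EQUATION_IDS",
]


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class EnergyUnit(str, enum.Enum):
    kcal_per_day = "kcal_per_day"
    kJ_per_day = "kJ_per_day"
    MJ_per_day = "MJ_per_day"


def convert_energy(
    value: float,
    from_unit: EnergyUnit | str,
    to_unit: EnergyUnit | str,
    kj_per_kcal: float = DEFAULT_SETTINGS.kj_per_kcal,
) -> float:
    """Convert an energy rate between kcal/d, kJ/d and MJ/d.

    Uses the thermochemical calorie (4.184 kJ/kcal) by default; the constant
    is exposed for sensitivity checks.
    """
    try:
        fu = EnergyUnit(from_unit)
        tu = EnergyUnit(to_unit)
    except ValueError as exc:
        raise ConfigurationError(f"unknown energy unit: {exc}") from None
    in_kcal = {
        EnergyUnit.kcal_per_day: 1.0,
        EnergyUnit.kJ_per_day: 1.0 / kj_per_kcal,
        EnergyUnit.MJ_per_day: 1000.0 / kj_per_kcal,
    }
    return value * in_kcal[fu] / in_kcal[tu]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

#: Subject fields an equation may require beyond the always-present basics.
OPTIONAL_FIELDS = ("fat_mass", "fat_free_mass")


@dataclass(frozen=True)
class Subject:
    """One participant: anthropometry, body composition and measured REE.

    ``fat_mass``, ``fat_free_mass``, ``measured_ree``, ``bmi_z`` and
    ``bmi_group`` may be absent (``None``).  Synthetic Gaussian cohorts can
    carry physiologically impossible values (e.g. negative fat mass) by
    design; range screening is a cohort-level quality report, not a hard
    constructor error (see :meth:`Cohort.quality`).
    """

    id: str
    sex: Sex
    age: float
    weight: float
    height: float
    fat_mass: float | None = None
    fat_free_mass: float | None = None
    measured_ree: float | None = None
    bmi_z: float | None = None
    bmi_group: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "sex", Sex(self.sex))
        if not math.isfinite(self.age):
            raise DomainError(f"subject {self.id}: age must be finite, got {self.age}")
        if not self.height > 0:
            raise DomainError(
                f"subject {self.id}: height must be > 0, got {self.height}"
            )

    @property
    def bmi(self) -> float:
        """Body mass index, kg/m^2 (weight over squared height in meters)."""
        return self.weight / (self.height / 100.0) ** 2

    def mass_consistent(self, tolerance: float = DEFAULT_SETTINGS.mass_tolerance) -> bool:
        """Whether weight ~= fat_mass + fat_free_mass (when all present)."""
        if self.fat_mass is None or self.fat_free_mass is None:
            return True
        return abs(self.weight - (self.fat_mass + self.fat_free_mass)) <= tolerance


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of subjects with unique ids plus a provenance note."""

    subjects: tuple[Subject, ...]
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "subjects", tuple(self.subjects))
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DomainError(f"duplicate subject ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the standard cohort CSV column names."""
        rows = [
            {
                "id": s.id,
                "sex": s.sex.value,
                "age_years": s.age,
                "weight_kg": s.weight,
                "height_cm": s.height,
                "fat_mass_kg": s.fat_mass,
                "fat_free_mass_kg": s.fat_free_mass,
                "measured_ree_kcal_d": s.measured_ree,
                "bmi_z": s.bmi_z,
                "bmi_group": s.bmi_group,
            }
            for s in self.subjects
        ]
        return pd.DataFrame(rows)

    def quality(self, mass_tolerance: float = DEFAULT_SETTINGS.mass_tolerance) -> dict:
        """Screen for out-of-range values; counts, never exceptions.

        Gaussian synthetic cohorts legitimately contain a few percent of
        negative fat-mass draws — this report is how that caveat surfaces.
        """
        n = len(self.subjects)
        counts = {
            "n": n,
            "negative_fat_mass": sum(
                1 for s in self.subjects if s.fat_mass is not None and s.fat_mass < 0
            ),
            "nonpositive_fat_free_mass": sum(
                1
                for s in self.subjects
                if s.fat_free_mass is not None and s.fat_free_mass <= 0
            ),
            "nonpositive_weight": sum(1 for s in self.subjects if s.weight <= 0),
            "negative_age": sum(1 for s in self.subjects if s.age < 0),
            "mass_inconsistent": sum(
                1 for s in self.subjects if not s.mass_consistent(mass_tolerance)
            ),
        }
        counts["negative_fat_mass_fraction"] = (
            counts["negative_fat_mass"] / n if n else 0.0
        )
        return counts


@dataclass(frozen=True)
class Variant:
    """One (sex filter, age bracket) row of an equation.

    ``sex`` of ``None`` means the row applies to both sexes.  ``coefficients``
    maps predictor names (``weight``, ``height_cm``, ``height_m``, ``age``,
    ``sex``, ``fat_mass``, ``fat_free_mass``) plus ``intercept`` to the
    published values in the equation's native unit.
    """

    sex: Sex | None
    age_lo: float
    age_hi: float
    coefficients: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "coefficients", dict(self.coefficients))
        unknown = set(self.coefficients) - set(_PREDICTOR_SOURCES) - {"intercept"}
        if unknown:
            raise ConfigurationError(f"unknown predictor(s) {sorted(unknown)}")


@dataclass(frozen=True)
class EquationSpec:
    """A complete prediction equation: variants, unit and sex coding."""

    equation_id: str
    label: str
    year: int
    variants: tuple[Variant, ...]
    native_unit: EnergyUnit
    sex_code: Mapping[Sex, int]
    stated_age_range: tuple[float, float]

    def __post_init__(self):
        object.__setattr__(self, "variants", tuple(self.variants))
        object.__setattr__(self, "sex_code", dict(self.sex_code))
        if set(self.sex_code) != {Sex.male, Sex.female}:
            raise ConfigurationError(
                f"{self.equation_id}: sex_code must map both sexes"
            )
        # variants must not overlap in (sex, age)
        for sex in (Sex.male, Sex.female):
            spans = sorted(
                (v.age_lo, v.age_hi) for v in self.variants if v.sex in (None, sex)
            )
            for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
                if lo2 < hi1:
                    raise ConfigurationError(
                        f"{self.equation_id}: overlapping variants for {sex.value}"
                    )

    @property
    def required_fields(self) -> frozenset[str]:
        """Subject fields any variant's coefficients reference."""
        fields = set()
        for v in self.variants:
            for name in v.coefficients:
                if name == "intercept":
                    continue
                fields.add(_PREDICTOR_SOURCES[name])
        return frozenset(fields)

    # -- JSON schema shared with user-developed equations -------------------

    def to_dict(self) -> dict:
        return {
            "equation_id": self.equation_id,
            "label": self.label,
            "year": self.year,
            "native_unit": self.native_unit.value,
            "sex_code": {s.value: c for s, c in self.sex_code.items()},
            "stated_age_range": list(self.stated_age_range),
            "variants": [
                {
                    "sex": v.sex.value if v.sex is not None else None,
                    "age_lo": v.age_lo,
                    "age_hi": v.age_hi,
                    "coefficients": dict(v.coefficients),
                }
                for v in self.variants
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EquationSpec":
        try:
            return cls(
                equation_id=d["equation_id"],
                label=d.get("label", d["equation_id"]),
                year=int(d.get("year", 0)),
                variants=tuple(
                    Variant(
                        sex=Sex(v["sex"]) if v["sex"] is not None else None,
                        age_lo=float(v["age_lo"]),
                        age_hi=float(v["age_hi"]),
                        coefficients={k: float(c) for k, c in v["coefficients"].items()},
                    )
                    for v in d["variants"]
                ),
                native_unit=EnergyUnit(d["native_unit"]),
                sex_code={Sex(s): int(c) for s, c in d["sex_code"].items()},
                stated_age_range=tuple(d["stated_age_range"]),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ConfigurationError(f"malformed equation spec: {exc!r}") from None


@dataclass(frozen=True)
class Prediction:
    """One equation applied to one subject, normalized to kcal/d."""

    subject_id: str
    equation_id: str
    predicted_ree: float
    native_value: float
    native_unit: EnergyUnit
    out_of_stated_range: bool


# how each predictor name is read off a Subject
_PREDICTOR_SOURCES = {
    "weight": "weight",
    "height_cm": "height",
    "height_m": "height",
    "age": "age",
    "sex": "sex",
    "fat_mass": "fat_mass",
    "fat_free_mass": "fat_free_mass",
}


def _predictor_value(subject: Subject, name: str, spec: EquationSpec) -> float:
    if name == "weight":
        return subject.weight
    if name == "height_cm":
        return subject.height
    if name == "height_m":
        return subject.height / 100.0
    if name == "age":
        return subject.age
    if name == "sex":
        return float(spec.sex_code[subject.sex])
    value = getattr(subject, name)  # fat_mass / fat_free_mass
    if value is None:
        raise InapplicableError(name, spec.equation_id)
    return value


def _dispatch(spec: EquationSpec, subject: Subject, settings: Settings) -> Variant:
    candidates = sorted(
        (v for v in spec.variants if v.sex in (None, subject.sex)),
        key=lambda v: v.age_lo,
    )
    if not candidates:
        raise DispatchError(
            f"{spec.equation_id}: no variant for sex={subject.sex.value}"
        )
    age = subject.age
    for v in candidates:
        at_boundary_goes_down = settings.age_boundary_to_lower and age == v.age_hi
        if age < v.age_hi or at_boundary_goes_down:
            return v
    return candidates[-1]  # above every bracket: oldest variant, flagged


def predict_ree(
    spec: EquationSpec,
    subject: Subject,
    settings: Settings = DEFAULT_SETTINGS,
) -> Prediction:
    """Evaluate one equation for one subject, returning kcal/day.

    Subjects outside the equation's stated age range are evaluated with the
    nearest age bracket and flagged ``out_of_stated_range`` (the validation
    tables cover every equation for the whole cohort); ``settings.strict_age_range``
    turns the flag into a :class:`DispatchError`.
    """
    lo, hi = spec.stated_age_range
    out_of_range = not (lo <= subject.age <= hi)
    if out_of_range and settings.strict_age_range:
        raise DispatchError(
            f"{spec.equation_id}: subject {subject.id} age {subject.age} outside "
            f"stated range [{lo}, {hi}] (strict mode)"
        )
    variant = _dispatch(spec, subject, settings)
    native = variant.coefficients.get("intercept", 0.0)
    for name, coef in variant.coefficients.items():
        if name == "intercept":
            continue
        native += coef * _predictor_value(subject, name, spec)
    kcal = convert_energy(
        native, spec.native_unit, EnergyUnit.kcal_per_day, settings.kj_per_kcal
    )
    return Prediction(
        subject_id=subject.id,
        equation_id=spec.equation_id,
        predicted_ree=kcal,
        native_value=native,
        native_unit=spec.native_unit,
        out_of_stated_range=out_of_range,
    )


PREDICTION_COLUMNS = [
    "id",
    "equation_id",
    "predicted_ree_kcal_d",
    "native_value",
    "native_unit",
    "out_of_stated_range",
    "inapplicable_reason",
]


def predict_all(
    cohort: Cohort,
    equation_ids: Sequence[str] | None = None,
    settings: Settings = DEFAULT_SETTINGS,
    specs: Iterable[EquationSpec] | None = None,
) -> pd.DataFrame:
    """Apply equations to every subject; inapplicable pairs are kept with a reason.

    Returns a frame with one row per (subject, equation); rows where a
    required field is missing carry ``inapplicable_reason`` and a NaN
    prediction instead of being dropped.
    """
    if len(cohort) == 0:
        raise DomainError("empty cohort")
    registry = {s.equation_id: s for s in (specs or equation_registry())}
    if equation_ids is None:
        equation_ids = list(registry)
    unknown = [e for e in equation_ids if e not in registry]
    if unknown:
        raise ConfigurationError(f"unknown equation id(s): {unknown}")
    rows = []
    for subject in cohort:
        for eq_id in equation_ids:
            spec = registry[eq_id]
            try:
                p = predict_ree(spec, subject, settings)
            except (InapplicableError, DispatchError) as exc:
                rows.append(
                    {
                        "id": subject.id,
                        "equation_id": eq_id,
                        "predicted_ree_kcal_d": float("nan"),
                        "native_value": float("nan"),
                        "native_unit": spec.native_unit.value,
                        "out_of_stated_range": False,
                        "inapplicable_reason": str(exc),
                    }
                )
            else:
                rows.append(
                    {
                        "id": p.subject_id,
                        "equation_id": p.equation_id,
                        "predicted_ree_kcal_d": p.predicted_ree,
                        "native_value": p.native_value,
                        "native_unit": p.native_unit.value,
                        "out_of_stated_range": p.out_of_stated_range,
                        "inapplicable_reason": None,
                    }
                )
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


# ---------------------------------------------------------------------------
# The registry: coefficients exactly as published
# ---------------------------------------------------------------------------

_M = Sex.male
_F = Sex.female
_M0F1 = {Sex.male: 0, Sex.female: 1}
_M1F0 = {Sex.male: 1, Sex.female: 0}
_KCAL = EnergyUnit.kcal_per_day
_KJ = EnergyUnit.kJ_per_day
_MJ = EnergyUnit.MJ_per_day


def _build_registry() -> tuple[EquationSpec, ...]:
    specs = [
        EquationSpec(
            "who", "WHO/FAO/UNU", 1985,
            (
                Variant(_M, 3, 10, {"weight": 22.7, "intercept": 495}),
                Variant(_F, 3, 10, {"weight": 22.5, "intercept": 499}),
                Variant(_M, 10, 18, {"weight": 18.4, "intercept": 651}),
                Variant(_F, 10, 18, {"weight": 12.5, "intercept": 746}),
            ),
            _KCAL, _M0F1, (3, 18),
        ),
        EquationSpec(
            "schofield", "Schofield", 1985,
            (
                Variant(_M, 3, 10, {"weight": 19.589, "height_cm": 1.302, "intercept": 414.7}),
                Variant(_F, 3, 10, {"weight": 16.961, "height_cm": 1.617, "intercept": 371.0}),
                Variant(_M, 10, 18, {"weight": 16.245, "height_cm": 1.371, "intercept": 515.3}),
                Variant(_F, 10, 18, {"weight": 8.361, "height_cm": 4.654, "intercept": 200.0}),
            ),
            _KCAL, _M0F1, (3, 18),
        ),
        EquationSpec(
            "iom", "IOM", 2004,
            (
                Variant(_M, 3, 18, {"intercept": 68, "age": -43.3, "height_cm": 7.12, "weight": 19.2}),
                Variant(_F, 3, 18, {"intercept": 189, "age": -17.6, "height_cm": 6.25, "weight": 7.9}),
            ),
            _KCAL, _M0F1, (3, 18),
        ),
        EquationSpec(
            "kim", "Kim", 2009,
            (Variant(None, 4, 11, {"intercept": 632.4, "age": 15.66, "weight": 9.53}),),
            _KCAL, _M0F1, (4, 11),
        ),
        EquationSpec(
            "henry", "Henry", 2005,
            (
                Variant(_M, 3, 10, {"weight": 15.1, "height_cm": 0.742, "intercept": 306}),
                Variant(_F, 3, 10, {"weight": 15.9, "height_cm": 2.1, "intercept": 349}),
                Variant(_M, 10, 18, {"weight": 15.6, "height_cm": 2.66, "intercept": 299}),
                Variant(_F, 10, 18, {"weight": 9.40, "height_cm": 2.49, "intercept": 462}),
            ),
            _KCAL, _M0F1, (3, 18),
        ),
        EquationSpec(
            "molnar", "Molnar", 1995,
            (
                Variant(None, 10, 16, {
                    "weight": 50.2, "height_cm": 29.6, "age": -144.5,
                    "sex": -550, "intercept": 594.3,
                }),
            ),
            _KJ, _M0F1, (10, 16),
        ),
        EquationSpec(
            "muller_a", "Muller (weight/height)", 2004,
            (
                Variant(None, 5, 17, {
                    "weight": 0.02606, "height_cm": 0.04129, "sex": 0.311,
                    "age": -0.08369, "intercept": -0.808,
                }),
            ),
            _MJ, _M0F1, (5, 17),
        ),
        EquationSpec(
            "muller_b", "Muller (FFM)", 2004,
            (
                Variant(None, 5, 17, {
                    "fat_free_mass": 0.07885, "fat_mass": 0.02132,
                    "sex": 0.327, "intercept": 2.694,
                }),
            ),
            _MJ, _M0F1, (5, 17),
        ),
        EquationSpec(
            "derumeaux_burel", "Derumeaux-Burel", 2004,
            (
                Variant(None, 3, 18, {
                    "fat_free_mass": 0.1371, "age": -0.1644, "intercept": 3.3647,
                }),
            ),
            _MJ, _M0F1, (3, 18),
        ),
        EquationSpec(
            "schmelzle", "Schmelzle", 2004,
            (
                Variant(_M, 4, 15, {"weight": 6.6, "height_cm": 13.1, "intercept": -794}),
                Variant(_F, 4, 15, {"weight": 11.9, "height_cm": 0.84, "intercept": 579}),
            ),
            _KCAL, _M0F1, (4, 15),
        ),
        EquationSpec(
            "tverskaya", "Tverskaya", 1998,
            (
                Variant(None, 6, 18, {
                    "intercept": 775, "fat_free_mass": 28.4, "age": -37,
                    "fat_mass": 3.3, "sex": 82,
                }),
            ),
            _KCAL, _M1F0, (6, 18),
        ),
        EquationSpec(
            "lazzer_a", "Lazzer (weight/height)", 2006,
            (
                Variant(None, 6, 18, {
                    "sex": 892.68, "age": -115.93, "weight": 54.96,
                    "height_m": 1816.23, "intercept": 1454.50,
                }),
            ),
            _KJ, _M1F0, (6, 18),
        ),
        EquationSpec(
            "lazzer_b", "Lazzer (FFM)", 2006,
            (
                Variant(None, 6, 18, {
                    "sex": 909.12, "age": -107.48, "fat_free_mass": 68.39,
                    "fat_mass": 55.19, "intercept": 3631.23,
                }),
            ),
            _KJ, _M1F0, (6, 18),
        ),
        EquationSpec(
            "new_ffm", "New FFM equation", 2023,
            (Variant(None, 6, 18, {"intercept": 505.412, "fat_free_mass": 24.383}),),
            _KCAL, _M1F0, (6, 18),
        ),
    ]
    return tuple(specs)


_REGISTRY: tuple[EquationSpec, ...] = _build_registry()

EQUATION_IDS: tuple[str, ...] = tuple(s.equation_id for s in _REGISTRY)


def equation_registry() -> tuple[EquationSpec, ...]:
    """The immutable registry of all 14 equations."""
    return _REGISTRY


def get_equation(equation_id: str) -> EquationSpec:
    for spec in _REGISTRY:
        if spec.equation_id == equation_id:
            return spec
    raise ConfigurationError(f"unknown equation id: {equation_id!r}")


def registry_digest() -> str:
    """Stable hash of the registry contents (provenance for reports)."""
    payload = json.dumps([s.to_dict() for s in _REGISTRY], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
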