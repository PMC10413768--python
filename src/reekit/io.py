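"""File round-tripping: cohort CSVs, equation specs, reports.

Cohort CSVs use the fixed column set
``id,sex,age_years,weight_kg,height_cm,fat_mass_kg,fat_free_mass_kg,
measured_ree_kcal_d,bmi_z,bmi_group`` with "." decimals and empty cells for
absent values.  Lines starting with ``#`` are comments (the generator writes
its config digest there).  Sex is always the string "male"/"female" in
files; per-equation numeric sex codings never leak into data files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .equations import Cohort, EquationSpec, Sex, Subject
from .exceptions import ConfigurationError, DomainError

COHORT_COLUMNS = [
    "id",
    "sex",
    "age_years",
    "weight_kg",
    "height_cm",
    "fat_mass_kg",
    "fat_free_mass_kg",
    "measured_ree_kcal_d",
    "bmi_z",
    "bmi_group",
]

_REQUIRED = ["id", "sex", "age_years", "weight_kg", "height_cm"]


def _opt(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return value


def cohort_from_frame(frame: pd.DataFrame, provenance: str = "") -> Cohort:
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"cohort table missing columns: {missing}")
    subjects = []
    for rec in frame.to_dict("records"):
        for col in _REQUIRED:
            if _opt(rec.get(col)) is None:
                raise DomainError(
                    f"cohort row id={rec.get('id')!r}: required column "
                    f"'{col}' is empty"
                )
        group = _opt(rec.get("bmi_group"))
        subjects.append(
            Subject(
                id=str(rec["id"]),
                sex=Sex(rec["sex"]),
                age=float(rec["age_years"]),
                weight=float(rec["weight_kg"]),
                height=float(rec["height_cm"]),
                fat_mass=_opt(rec.get("fat_mass_kg")),
                fat_free_mass=_opt(rec.get("fat_free_mass_kg")),
                measured_ree=_opt(rec.get("measured_ree_kcal_d")),
                bmi_z=_opt(rec.get("bmi_z")),
                bmi_group=str(group) if group is not None else None,
            )
        )
    return Cohort(subjects=tuple(subjects), provenance=provenance)


def read_cohort(path) -> Cohort:
    """Load a cohort CSV; ``#`` lines are comments, empty cells are absent."""
    path = Path(path)
    frame = pd.read_csv(path, comment="#")
    return cohort_from_frame(frame, provenance=str(path))


def write_cohort(cohort: Cohort, path, header_comment: str | None = None) -> None:
    """Write the standard cohort CSV, with provenance as a comment line."""
    path = Path(path)
    frame = cohort.to_frame()[COHORT_COLUMNS]
    comment = header_comment if header_comment is not None else cohort.provenance
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        frame.to_csv(fh, index=False)


def write_predictions(predictions: pd.DataFrame, path) -> None:
    predictions.to_csv(path, index=False)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_validation_report(validation: pd.DataFrame, path) -> None:
    validation.to_csv(path, index=False)


def write_equation_spec(spec: EquationSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2)
        fh.write("\n")


def read_equation_spec(path) -> EquationSpec:
    with open(path) as fh:
        return EquationSpec.from_dict(json.load(fh))


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
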