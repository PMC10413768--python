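"""Tunable defaults shared across the pipeline.

Every knob documented as a design decision lives here with its default, so a
single :class:`Settings` instance fully determines pipeline behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

#: Thermochemical calorie: kilojoules per kilocalorie.
KJ_PER_KCAL = 4.184


@dataclass(frozen=True)
class Settings:
    """All pipeline tunables with their documented defaults.

    Attributes
    ----------
    kj_per_kcal:
        Energy conversion constant (thermochemical calorie).
    age_boundary_to_lower:
        Age-bracket boundary rule for split equations (child 3-10 /
        adolescent 10-18 variants).  ``False`` (default): a subject exactly at
        the boundary age uses the older bracket (age >= 10 -> adolescent).
        ``True`` flips the rule.
    strict_age_range:
        If ``True``, refuse to evaluate an equation for subjects outside its
        stated age range instead of flagging the prediction.
    accuracy_inclusive:
        Whether predicted/measured ratios of exactly 0.90 or 1.10 count as
        accurate predictions.
    ba_multiplier:
        Multiplier of the SD of differences for Bland-Altman limits of
        agreement (2.0, not 1.96).
    screen_alpha:
        Univariate significance threshold for entering the multivariate model.
    removal_alpha:
        Backward-elimination removal threshold.
    mass_tolerance:
        Allowed |weight - (fat_mass + fat_free_mass)| in kg when all three
        are present.
    """

    kj_per_kcal: float = KJ_PER_KCAL
    age_boundary_to_lower: bool = False
    strict_age_range: bool = False
    accuracy_inclusive: bool = True
    ba_multiplier: float = 2.0
    screen_alpha: float = 0.05
    removal_alpha: float = 0.05
    mass_tolerance: float = 1.0

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_SETTINGS = Settings()
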