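"""Calibrated synthetic cohort generation.

The generator draws (age, height, FFM, FM) from a multivariate Gaussian
whose moments and correlation structure are calibrated so that the cohort
reproduces, as emergent properties: the published marginal means/SDs, the
weight SD via weight = FFM + FM, and the univariate R² of measured REE on
FFM / weight / height / age.  Measured REE is generated from the linear
model

    REE = 505.412 + 24.383 * FFM + eps,   eps ~ N(0, sigma_eps)

with sigma_eps derived from the variance identity
sigma_REE² = slope² * sigma_FFM² + sigma_eps².

Three correlation entries — (FFM, FM), (FFM, age), (FFM, height) — are
back-solved from published summary statistics; the remaining three
(age-height, age-FM, height-FM) are free plausibility choices that no
calibration target depends on.

Gaussian mode applies no truncation (so moment recovery is exact in
expectation) and therefore produces a few percent of negative fat-mass
draws, reported via :meth:`reekit.equations.Cohort.quality`.  Realistic mode
resamples ages into [6, 18] and clips FM/FFM away from zero; it is for
demos, not calibration checks.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .equations import Cohort, Sex, Subject
from .exceptions import CalibrationError, ConfigurationError, DomainError

__all__ = [
    "GeneratorConfig",
    "derive_noise_sd",
    "default_correlations",
    "simulate_cohort",
    "assign_groups",
    "LATENT_VARIABLES",
]

#: Order of the latent Gaussian block.
LATENT_VARIABLES = ("age", "height", "ffm", "fm")

# Published cohort summary statistics the calibration reproduces.
_MEANS = {"age": 11.8, "height": 153.0, "ffm": 41.6, "fm": 15.2}
_SDS = {"age": 3.19, "height": 17.11, "ffm": 14.01, "fm": 9.58}
_SD_REE = 423.69
_SD_WEIGHT = 20.71
_TRUE_INTERCEPT = 505.412
_TRUE_SLOPE = 24.383


def derive_noise_sd(
    sd_ree: float = _SD_REE,
    slope: float = _TRUE_SLOPE,
    sd_ffm: float = _SDS["ffm"],
) -> float:
    """Residual SD implied by sigma_REE² = slope²·sigma_FFM² + sigma_eps²."""
    if not (sd_ffm > 0 and slope >= 0):
        raise CalibrationError("need sd_ffm > 0 and slope >= 0")
    explained = slope * sd_ffm
    if explained >= sd_ree:
        raise CalibrationError(
            f"infeasible calibration: slope*sd_ffm = {explained:.4g} >= "
            f"sd_ree = {sd_ree:.4g}"
        )
    return math.sqrt(sd_ree**2 - explained**2)


def default_correlations() -> np.ndarray:
    """Default correlation matrix over (age, height, ffm, fm).

    The three FFM entries are back-solved from published summaries (weight
    variance identity and univariate R² algebra); the other three are free
    plausibility parameters.
    """
    rho = {
        ("ffm", "fm"): 0.525,  # from sd_w² = sd_ffm² + sd_fm² + 2 rho sd_ffm sd_fm
        ("ffm", "age"): 0.760,  # from R²(REE~age) = (rho * k)², k = slope*sd_ffm/sd_ree
        ("ffm", "height"): 0.927,  # same algebra with R²(REE~height)
        ("age", "height"): 0.85,  # free
        ("age", "fm"): 0.35,  # free
        ("height", "fm"): 0.40,  # free
    }
    n = len(LATENT_VARIABLES)
    mat = np.eye(n)
    for (a, b), r in rho.items():
        i, j = LATENT_VARIABLES.index(a), LATENT_VARIABLES.index(b)
        mat[i, j] = mat[j, i] = r
    return mat


def _check_correlations(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    k = len(LATENT_VARIABLES)
    if mat.shape != (k, k):
        raise ConfigurationError(f"correlation matrix must be {k}x{k}")
    if not np.allclose(mat, mat.T):
        raise ConfigurationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0):
        raise ConfigurationError("correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh(mat).min() <= 0:
        raise ConfigurationError("correlation matrix must be positive definite")
    return mat


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of a synthetic cohort draw.

    ``seed`` is mandatory; every other field defaults to the calibrated
    values.  ``noise_sd=None`` means "derive from the variance identity".
    """

    seed: int
    n: int = 275
    male_fraction: float = 148 / 275
    means: dict = field(default_factory=lambda: dict(_MEANS))
    sds: dict = field(default_factory=lambda: dict(_SDS))
    correlations: tuple = field(
        default_factory=lambda: tuple(map(tuple, default_correlations()))
    )
    intercept: float = _TRUE_INTERCEPT
    slope: float = _TRUE_SLOPE
    noise_sd: float | None = None
    sd_ree: float = _SD_REE
    group_sizes: tuple[int, int, int] = (105, 52, 118)  # normal, overweight, obese
    mode: str = "gaussian"

    def __post_init__(self):
        if self.mode not in ("gaussian", "realistic"):
            raise ConfigurationError(f"unknown mode: {self.mode!r}")
        if set(self.means) != set(LATENT_VARIABLES) or set(self.sds) != set(
            LATENT_VARIABLES
        ):
            raise ConfigurationError(
                f"means/sds must be keyed by {LATENT_VARIABLES}"
            )
        if any(sd <= 0 for sd in self.sds.values()):
            raise ConfigurationError("all SDs must be > 0")
        if not 0 <= self.male_fraction <= 1:
            raise ConfigurationError("male_fraction must be in [0, 1]")
        _check_correlations(np.asarray(self.correlations))

    @property
    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return derive_noise_sd(self.sd_ree, self.slope, self.sds["ffm"])

    def correlation_matrix(self) -> np.ndarray:
        return np.asarray(self.correlations, dtype=float)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n": self.n,
            "male_fraction": self.male_fraction,
            "means": dict(self.means),
            "sds": dict(self.sds),
            "correlations": [list(r) for r in self.correlations],
            "intercept": self.intercept,
            "slope": self.slope,
            "noise_sd": self.noise_sd,
            "sd_ree": self.sd_ree,
            "group_sizes": list(self.group_sizes),
            "mode": self.mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "correlations" in d:
            d["correlations"] = tuple(map(tuple, d["correlations"]))
        if "group_sizes" in d:
            d["group_sizes"] = tuple(d["group_sizes"])
        return cls(**d)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _draw_latent(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    mu = np.array([config.means[v] for v in LATENT_VARIABLES])
    sd = np.array([config.sds[v] for v in LATENT_VARIABLES])
    cov = config.correlation_matrix() * np.outer(sd, sd)
    if config.mode == "gaussian":
        return rng.multivariate_normal(mu, cov, size=config.n, method="cholesky")
    # realistic mode: reject rows with age outside [6, 18], then clip masses
    rows = []
    needed = config.n
    while needed > 0:
        batch = rng.multivariate_normal(mu, cov, size=max(needed * 2, 16), method="cholesky")
        ok = batch[(batch[:, 0] >= 6) & (batch[:, 0] <= 18)]
        rows.append(ok[:needed])
        needed -= len(ok[:needed])
    latent = np.vstack(rows)
    latent[:, 2] = np.maximum(latent[:, 2], 0.5)  # ffm
    latent[:, 3] = np.maximum(latent[:, 3], 0.5)  # fm
    return latent


def simulate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a fully reproducible synthetic cohort from ``config``.

    Weight is FFM + FM exactly; measured REE comes from the configured linear
    model plus Gaussian noise; sex is Bernoulli(male_fraction), independent
    of body composition.
    """
    if config.n < 10:
        raise DomainError(
            f"refusing to simulate n={config.n} < 10: moment checks are meaningless"
        )
    rng = np.random.default_rng(config.seed)
    latent = _draw_latent(config, rng)
    age, height, ffm, fm = latent.T
    male = rng.random(config.n) < config.male_fraction
    noise = rng.normal(0.0, config.resolved_noise_sd, size=config.n)
    ree = config.intercept + config.slope * ffm + noise
    weight = ffm + fm
    width = len(str(config.n))
    subjects = tuple(
        Subject(
            id=f"S{i + 1:0{width}d}",
            sex=Sex.male if male[i] else Sex.female,
            age=float(age[i]),
            weight=float(weight[i]),
            height=float(height[i]),
            fat_mass=float(fm[i]),
            fat_free_mass=float(ffm[i]),
            measured_ree=float(ree[i]),
        )
        for i in range(config.n)
    )
    return Cohort(subjects=subjects, provenance=f"generator:{config.digest()}")


def assign_groups(
    cohort: Cohort, group_sizes: tuple[int, int, int] = (105, 52, 118)
) -> Cohort:
    """Label BMI groups by rank of age-adjusted BMI.

    Subjects are ranked by the residual of BMI regressed on age (OLS); the
    top ``group_sizes[2]`` become obese, the next ``group_sizes[1]``
    overweight, the rest normal.  Ties break on subject id, so the labels do
    not depend on subject order.
    """
    n_normal, n_over, n_obese = group_sizes
    if n_normal + n_over + n_obese != len(cohort):
        raise DomainError(
            f"group sizes {group_sizes} do not sum to cohort size {len(cohort)}"
        )
    subjects = list(cohort)
    bmi = np.array([s.weight / (s.height / 100.0) ** 2 for s in subjects])
    age = np.array([s.age for s in subjects])
    design = np.column_stack([np.ones(len(subjects)), age])
    beta, *_ = np.linalg.lstsq(design, bmi, rcond=None)
    resid = bmi - design @ beta
    order = sorted(range(len(subjects)), key=lambda i: (-resid[i], subjects[i].id))
    labels = {}
    for rank, i in enumerate(order):
        if rank < n_obese:
            labels[i] = "obese"
        elif rank < n_obese + n_over:
            labels[i] = "overweight"
        else:
            labels[i] = "normal"
    relabeled = tuple(
        replace(s, bmi_group=labels[i]) for i, s in enumerate(subjects)
    )
    return Cohort(subjects=relabeled, provenance=cohort.provenance)
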