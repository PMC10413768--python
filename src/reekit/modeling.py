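"""Equation development: univariate screening and backward stepwise OLS.

The procedure mirrors the classic biostatistics workflow: regress the
response on each candidate alone, keep candidates with univariate p <= 0.05,
fit the multivariate model, and repeatedly remove the predictor with the
largest p-value above the removal threshold until all retained coefficients
are significant.  Exact linear dependencies (e.g. weight = FFM + FM, as
produced by bioimpedance decompositions) are resolved by rank inspection
before elimination begins, dropping the aliased predictor with the weakest
univariate R².

Fits are ordinary least squares via statsmodels; tests cross-check them
against an explicit normal-equations solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import DEFAULT_SETTINGS, Settings
from .equations import EnergyUnit, EquationSpec, Sex, Variant
from .exceptions import ConfigurationError, DegenerateDataError

__all__ = [
    "RegressionFit",
    "StepwiseResult",
    "univariate_fit",
    "multiple_fit",
    "screen_predictors",
    "backward_stepwise",
    "package_equation",
    "candidate_matrix",
    "CANDIDATE_PREDICTORS",
]

#: Candidate predictors of measured REE considered during development,
#: in the order they are screened.
CANDIDATE_PREDICTORS = (
    "sex",
    "age",
    "weight",
    "height",
    "bmi",
    "fat_free_mass",
    "fat_mass",
    "fat_pct",
)

#: Predictors that map directly onto subject fields and can therefore be
#: packaged into a deployable equation.
_PACKAGEABLE = {
    "age": "age",
    "weight": "weight",
    "height": "height_cm",
    "sex": "sex",
    "fat_free_mass": "fat_free_mass",
    "fat_mass": "fat_mass",
}


@dataclass(frozen=True)
class RegressionFit:
    """An OLS fit with intercept: estimates, 95% CIs, p-values and R²."""

    response: str
    predictors: tuple[str, ...]
    params: dict  # name -> estimate, including "intercept"
    conf_int: dict  # name -> (lower, upper), 95% two-sided
    pvalues: dict  # name -> two-sided p (t-test); intercept included
    r2: float
    adj_r2: float
    n: int
    resid_sd: float  # sqrt(SSR / (n - k - 1))
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        out = np.full(len(data), self.params["intercept"], dtype=float)
        for name in self.predictors:
            out += self.params[name] * data[name].to_numpy(dtype=float)
        return out

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "params": dict(self.params),
            "conf_int": {k: list(v) for k, v in self.conf_int.items()},
            "pvalues": dict(self.pvalues),
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "n": self.n,
            "resid_sd": self.resid_sd,
        }


def _fit_ols(X: pd.DataFrame, y: np.ndarray, response: str) -> RegressionFit:
    n = len(y)
    k = X.shape[1]
    if n < k + 2:
        raise DegenerateDataError(
            f"need at least {k + 2} observations for {k} predictor(s), got {n}"
        )
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    model = sm.OLS(np.asarray(y, dtype=float), design)
    res = model.fit()
    names = ["intercept"] + list(X.columns)
    ci = res.conf_int(alpha=0.05)
    return RegressionFit(
        response=response,
        predictors=tuple(X.columns),
        params={nm: float(v) for nm, v in zip(names, res.params)},
        conf_int={nm: (float(lo), float(hi)) for nm, (lo, hi) in zip(names, ci)},
        pvalues={nm: float(p) for nm, p in zip(names, res.pvalues)},
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        n=n,
        resid_sd=float(np.sqrt(res.mse_resid)),
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
    )


def univariate_fit(x, y, name: str = "x", response: str = "y") -> RegressionFit:
    """Simple linear regression of ``y`` on one predictor, with intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DegenerateDataError("x and y lengths differ")
    if len(x) < 3:
        raise DegenerateDataError("need n >= 3 for a univariate fit")
    if np.ptp(x) == 0:
        raise DegenerateDataError(f"predictor '{name}' has zero variance")
    return _fit_ols(pd.DataFrame({name: x}), y, response)


def multiple_fit(X: pd.DataFrame, y, response: str = "y") -> RegressionFit:
    """OLS of ``y`` on all columns of ``X``, with intercept.

    An empty ``X`` yields the intercept-only model.
    """
    y = np.asarray(y, dtype=float)
    if X.shape[1] == 0:
        n = len(y)
        mean = float(y.mean())
        resid = y - mean
        sd = float(np.sqrt(resid @ resid / (n - 1))) if n > 1 else 0.0
        import scipy.stats as st

        se = sd / np.sqrt(n) if n else float("nan")
        tcrit = st.t.ppf(0.975, n - 1) if n > 1 else float("nan")
        p = (
            2 * st.t.sf(abs(mean / se), n - 1)
            if n > 1 and se > 0
            else float("nan")
        )
        return RegressionFit(
            response=response,
            predictors=(),
            params={"intercept": mean},
            conf_int={"intercept": (mean - tcrit * se, mean + tcrit * se)},
            pvalues={"intercept": float(p)},
            r2=0.0,
            adj_r2=0.0,
            n=n,
            resid_sd=sd,
            fitted=np.full(n, mean),
            residuals=resid,
        )
    return _fit_ols(X, y, response)


def screen_predictors(fits: list[RegressionFit], alpha: float = 0.05) -> list[str]:
    """Names of predictors whose univariate slope p-value is <= alpha.

    Each fit must be univariate; order of the input list is preserved
    (``p == alpha`` is included).
    """
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    kept = []
    for fit in fits:
        if len(fit.predictors) != 1:
            raise ConfigurationError("screen_predictors expects univariate fits")
        name = fit.predictors[0]
        if fit.pvalues[name] <= alpha:
            kept.append(name)
    return kept


def _resolve_aliasing(
    X: pd.DataFrame, univariate_r2: dict[str, float]
) -> tuple[list[str], list[str]]:
    """Drop exactly collinear predictors (weakest univariate R² first)."""
    cols = list(X.columns)
    dropped: list[str] = []
    ones = np.ones((len(X), 1))

    def rank(cs):
        m = np.hstack([ones] + [X[c].to_numpy(dtype=float).reshape(-1, 1) for c in cs])
        return np.linalg.matrix_rank(m)

    while cols and rank(cols) < len(cols) + 1:
        full_rank = rank(cols)
        redundant = [c for c in cols if rank([d for d in cols if d != c]) == full_rank]
        if not redundant:  # pragma: no cover - rank() is monotone, can't happen
            break
        victim = min(redundant, key=lambda c: (univariate_r2.get(c, 0.0), c))
        cols.remove(victim)
        dropped.append(victim)
    return cols, dropped


@dataclass(frozen=True)
class StepwiseResult:
    """Outcome of screening + backward elimination."""

    screened: tuple[str, ...]  # predictors entering the multivariate model
    dropped_aliased: tuple[str, ...]  # removed for exact collinearity
    trace: tuple[tuple[str, float, int], ...]  # (predictor, p at removal, step)
    final: RegressionFit

    def to_dict(self) -> dict:
        return {
            "screened": list(self.screened),
            "dropped_aliased": list(self.dropped_aliased),
            "trace": [
                {"predictor": p, "p_at_removal": pv, "step": s}
                for p, pv, s in self.trace
            ],
            "final": self.final.to_dict(),
        }


def backward_stepwise(
    X: pd.DataFrame,
    y,
    removal_alpha: float = DEFAULT_SETTINGS.removal_alpha,
    response: str = "y",
) -> StepwiseResult:
    """Backward p-value elimination starting from all columns of ``X``.

    At each step the predictor with the largest p-value exceeding
    ``removal_alpha`` is removed and the model refit; the process stops when
    every retained coefficient has p <= ``removal_alpha`` or the model is
    empty (reported as intercept-only, not an error).  Deterministic given
    column order; ties in p broken by column name.
    """
    if not 0 < removal_alpha < 1:
        raise ConfigurationError(f"removal_alpha must be in (0, 1), got {removal_alpha}")
    if X.shape[1] == 0:
        raise ConfigurationError("backward_stepwise needs at least one predictor")
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1] + 2:
        raise DegenerateDataError(
            f"n={len(y)} too small for {X.shape[1]} predictors"
        )
    uni_r2 = {}
    for c in X.columns:
        x = X[c].to_numpy(dtype=float)
        uni_r2[c] = 0.0 if np.ptp(x) == 0 else univariate_fit(x, y, name=c).r2
    cols, dropped = _resolve_aliasing(X, uni_r2)

    trace: list[tuple[str, float, int]] = []
    step = 0
    while cols:
        fit = multiple_fit(X[cols], y, response=response)
        worst = max(
            cols, key=lambda c: (fit.pvalues[c], c)
        )  # name tie-break for determinism
        if fit.pvalues[worst] <= removal_alpha:
            break
        step += 1
        trace.append((worst, fit.pvalues[worst], step))
        cols.remove(worst)
    final = multiple_fit(X[cols], y, response=response)
    return StepwiseResult(
        screened=tuple(X.columns),
        dropped_aliased=tuple(dropped),
        trace=tuple(trace),
        final=final,
    )


def candidate_matrix(cohort, predictors=CANDIDATE_PREDICTORS) -> tuple[pd.DataFrame, np.ndarray]:
    """Design frame of candidate predictors plus the measured-REE response.

    Sex is coded male=1, female=0; ``bmi`` and ``fat_pct`` are derived from
    the stored anthropometry.  Subjects missing the response or a requested
    predictor are excluded.
    """
    frame = cohort.to_frame()
    frame = frame[frame["measured_ree_kcal_d"].notna()].reset_index(drop=True)
    data = pd.DataFrame(index=frame.index)
    for name in predictors:
        if name == "sex":
            data[name] = (frame["sex"] == "male").astype(float)
        elif name == "age":
            data[name] = frame["age_years"]
        elif name == "weight":
            data[name] = frame["weight_kg"]
        elif name == "height":
            data[name] = frame["height_cm"]
        elif name == "bmi":
            data[name] = frame["weight_kg"] / (frame["height_cm"] / 100.0) ** 2
        elif name == "fat_free_mass":
            data[name] = frame["fat_free_mass_kg"]
        elif name == "fat_mass":
            data[name] = frame["fat_mass_kg"]
        elif name == "fat_pct":
            data[name] = 100.0 * frame["fat_mass_kg"] / frame["weight_kg"]
        else:
            raise ConfigurationError(f"unknown candidate predictor: {name!r}")
    y = frame["measured_ree_kcal_d"].to_numpy(dtype=float)
    keep = data.notna().all(axis=1).to_numpy()
    return data.loc[keep].reset_index(drop=True), y[keep]


def package_equation(
    fit: RegressionFit,
    equation_id: str = "developed",
    label: str = "Developed equation",
    year: int = 0,
    stated_age_range: tuple[float, float] = (6, 18),
) -> EquationSpec:
    """Wrap a fitted model as an :class:`EquationSpec` usable by predict_ree.

    Only predictors that correspond to subject fields can be packaged;
    derived predictors (BMI, fat %) raise :class:`ConfigurationError`.  Sex
    is coded male=1, female=0, matching :func:`candidate_matrix`.
    """
    coefficients = {"intercept": fit.params["intercept"]}
    for name in fit.predictors:
        if name not in _PACKAGEABLE:
            raise ConfigurationError(
                f"predictor {name!r} is not a subject field and cannot be packaged"
            )
        coefficients[_PACKAGEABLE[name]] = fit.params[name]
    return EquationSpec(
        equation_id=equation_id,
        label=label,
        year=year,
        variants=(
            Variant(
                sex=None,
                age_lo=stated_age_range[0],
                age_hi=stated_age_range[1],
                coefficients=coefficients,
            ),
        ),
        native_unit=EnergyUnit.kcal_per_day,
        sex_code={Sex.male: 1, Sex.female: 0},
        stated_age_range=stated_age_range,
    )
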