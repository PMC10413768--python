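"""Recompute the headline recovery statistics from scratch.

Each function simulates calibrated synthetic cohorts with the default
generator configuration and measures a statistic of the published analysis:
the refit FFM equation's coefficients, adjusted R² and resubstitution RMSE,
the cohort mean REE, and the univariate slopes/R² for weight, height and
age.  Twenty-seed experiments use seeds ``base_seed .. base_seed + 19``.
"""

from __future__ import annotations

import numpy as np

from .metrics import rmse as _rmse
from .modeling import univariate_fit
from .synth import GeneratorConfig, simulate_cohort

N_SEEDS = 20


def _cohort_frame(seed: int, n: int = 275):
    return simulate_cohort(GeneratorConfig(seed=seed, n=n)).to_frame()


def _ffm_fit(frame):
    return univariate_fit(
        frame["fat_free_mass_kg"], frame["measured_ree_kcal_d"], name="ffm",
        response="measured_ree",
    )


def resubstitution_mean_difference(seed: int, n: int = 275) -> float:
    """t1: mean (predicted - measured) of the refit FFM equation, kcal/d."""
    frame = _cohort_frame(seed, n)
    fit = _ffm_fit(frame)
    return float(np.mean(fit.fitted - frame["measured_ree_kcal_d"].to_numpy()))


def ffm_refit_recovery(base_seed: int, n: int = 275, n_seeds: int = N_SEEDS) -> dict:
    """t2/t3/t4/t5: slope, intercept, adjusted R² and resubstitution RMSE,
    averaged over ``n_seeds`` cohorts."""
    slopes, intercepts, adj_r2s, rmses = [], [], [], []
    for seed in range(base_seed, base_seed + n_seeds):
        frame = _cohort_frame(seed, n)
        fit = _ffm_fit(frame)
        slopes.append(fit.params["ffm"])
        intercepts.append(fit.params["intercept"])
        adj_r2s.append(fit.adj_r2)
        measured = frame["measured_ree_kcal_d"].to_numpy()
        rmses.append(_rmse(np.column_stack([fit.fitted, measured])))
    return {
        "slope": float(np.mean(slopes)),
        "intercept": float(np.mean(intercepts)),
        "adj_r2": float(np.mean(adj_r2s)),
        "rmse": float(np.mean(rmses)),
    }


def cohort_mean_ree(seed: int, n: int = 275) -> float:
    """t6: sample mean of simulated measured REE for one default cohort."""
    return float(_cohort_frame(seed, n)["measured_ree_kcal_d"].mean())


def univariate_recovery(
    column: str, base_seed: int, n: int = 275, n_seeds: int = N_SEEDS
) -> dict:
    """t7-t10: mean univariate slope and R² of REE on one predictor column."""
    slopes, r2s = [], []
    for seed in range(base_seed, base_seed + n_seeds):
        frame = _cohort_frame(seed, n)
        fit = univariate_fit(
            frame[column], frame["measured_ree_kcal_d"], name=column,
            response="measured_ree",
        )
        slopes.append(fit.params[column])
        r2s.append(fit.r2)
    return {"slope": float(np.mean(slopes)), "r2": float(np.mean(r2s))}


def stepwise_sole_ffm_count(base_seed: int, n: int = 275, n_seeds: int = N_SEEDS) -> int:
    """Number of seeds for which backward stepwise ends with FFM alone."""
    from .modeling import backward_stepwise, candidate_matrix, screen_predictors

    count = 0
    for seed in range(base_seed, base_seed + n_seeds):
        cohort = simulate_cohort(GeneratorConfig(seed=seed, n=n))
        X, y = candidate_matrix(cohort)
        uni = [univariate_fit(X[c], y, name=c) for c in X.columns]
        screened = screen_predictors(uni)
        result = backward_stepwise(X[screened], y)
        count += result.final.predictors == ("fat_free_mass",)
    return count
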