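"""Early-vs-late foundress-stage comparisons.

Two mixed models with a per-queen random intercept:

- duration: linear mixed model on the natural log of foraging-trip duration,
  with stage (early/late) as the fixed effect — fitted with statsmodels
  MixedLM (REML);
- frequency: negative-binomial mixed model on daily trip counts, with stage
  as the fixed effect — fitted with the marginal-ML implementation in
  :mod:`queentrack.mixed_nb`.

Both report the Wald p-value of the stage coefficient and a Pearson
overdispersion statistic.  Stage is coded LATE = 1, so a positive duration
coefficient means longer late-stage trips and a negative frequency
coefficient means fewer late-stage trips per day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .mixed_nb import DegenerateFitError, MixedNB

__all__ = [
    "StageModelResult",
    "fit_duration_model",
    "fit_frequency_model",
    "check_overdispersion",
    "DegenerateFitError",
]

#: flag threshold for the Pearson statistic
OVERDISPERSION_FLAG = 1.5


@dataclass(frozen=True)
class StageModelResult:
    response: str
    stage_estimate: float      # LATE - EARLY on the model's link scale
    stage_se: float
    p_value: float
    intercept: float
    random_intercept_var: float
    n_obs: int
    n_queens: int
    overdispersion: float
    overdispersed: bool
    extra: dict

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def check_overdispersion(
    y: np.ndarray, mu: np.ndarray, var: np.ndarray, n_params: int
) -> float:
    """Pearson residual sum of squares over residual degrees of freedom.

    Values near 1 indicate the assumed variance function matches the data;
    values well above 1 flag overdispersion.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    dof = y.size - n_params
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    return float(np.sum((y - mu) ** 2 / var) / dof)


def _stage_design(df: pd.DataFrame, stage_col: str) -> np.ndarray:
    stages = set(df[stage_col].unique())
    if stages != {"EARLY", "LATE"}:
        raise ValueError(f"need both EARLY and LATE stages, got {sorted(stages)}")
    return (df[stage_col] == "LATE").to_numpy(dtype=float)


def fit_duration_model(staged_trips: pd.DataFrame) -> StageModelResult:
    """LMM: log(duration_s) ~ stage + (1 | queen_id).

    Expects columns queen_id, duration_s, stage (EARLY/LATE).  Durations
    must be positive.  Refuses single-queen input (random effect would be
    inestimable) and degenerate responses with zero variance.
    """
    df = staged_trips.copy()
    required = {"queen_id", "duration_s", "stage"}
    if missing := required - set(df.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise DegenerateFitError("no trips")
    if (df["duration_s"] <= 0).any():
        raise ValueError("durations must be positive")
    n_queens = df["queen_id"].nunique()
    if n_queens < 2:
        raise DegenerateFitError("random intercept needs at least two queens")
    y = np.log(df["duration_s"].to_numpy(dtype=float))
    if np.var(y) < 1e-12:
        raise DegenerateFitError("zero residual variance: all durations identical")
    late = _stage_design(df, "stage")
    exog = sm.add_constant(late)
    model = MixedLM(y, exog, groups=df["queen_id"].to_numpy())
    with warnings.catch_warnings():
        # boundary fits (random-intercept variance ~ 0) are legitimate here
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
        est, se = float(fit.fe_params[1]), float(fit.bse_fe[1])
        p = float(fit.pvalues[1])
    sigma2 = float(fit.scale)
    tau2 = float(np.asarray(fit.cov_re)[0, 0])
    mu_marg = exog @ np.asarray(fit.fe_params)
    healthy = (
        np.all(np.isfinite(np.asarray(fit.fe_params)))
        and np.all(np.isfinite(np.asarray(fit.bse_fe)))
        and np.isfinite(p)
        and tau2 > 0.0
    )
    if not healthy:
        # boundary fit (tau^2 -> 0): the model collapses to OLS, and the
        # singular mixed-model Hessian yields no usable estimates at all
        ols = sm.OLS(y, exog).fit()
        est, se, p = float(ols.params[1]), float(ols.bse[1]), float(ols.pvalues[1])
        sigma2, tau2 = float(ols.mse_resid), 0.0
        mu_marg = np.asarray(ols.fittedvalues)
        intercept = float(ols.params[0])
    else:
        intercept = float(fit.fe_params[0])
    # marginal residual check: total variance = residual + random-intercept
    od = check_overdispersion(y, mu_marg, np.full_like(y, sigma2 + tau2), n_params=2)
    return StageModelResult(
        response="log_duration",
        stage_estimate=est,
        stage_se=se,
        p_value=p,
        intercept=intercept,
        random_intercept_var=tau2,
        n_obs=len(df),
        n_queens=n_queens,
        overdispersion=od,
        overdispersed=od > OVERDISPERSION_FLAG,
        extra={"residual_var": sigma2, "duration_ratio_late_early": float(np.exp(est))},
    )


def fit_frequency_model(daily_counts: pd.DataFrame) -> StageModelResult:
    """NB GLMM: trips per day ~ stage + (1 | queen_id).

    Expects columns queen_id, n_trips, stage.  Counts must be non-negative
    integers; an all-zero response is a degenerate fit.
    """
    df = daily_counts.copy()
    required = {"queen_id", "n_trips", "stage"}
    if missing := required - set(df.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise DegenerateFitError("no daily counts")
    late = _stage_design(df, "stage")
    exog = np.column_stack([np.ones(len(df)), late])
    model = MixedNB(
        endog=df["n_trips"].to_numpy(),
        exog=exog,
        groups=df["queen_id"].to_numpy(),
        exog_names=["const", "stage_late"],
    )
    fit = model.fit()
    mu = model.fitted_means(fit)
    var = mu + mu**2 / fit.theta
    od = check_overdispersion(df["n_trips"].to_numpy(), mu, var, n_params=2)
    p = float(fit.wald_pvalues()[1])
    return StageModelResult(
        response="daily_trip_count",
        stage_estimate=float(fit.beta[1]),
        stage_se=float(fit.beta_se[1]),
        p_value=p,
        intercept=float(fit.beta[0]),
        random_intercept_var=fit.sigma**2,
        n_obs=fit.n_obs,
        n_queens=fit.n_groups,
        overdispersion=od,
        overdispersed=od > OVERDISPERSION_FLAG,
        extra={
            "nb_dispersion_theta": fit.theta,
            "rate_ratio_late_early": float(np.exp(fit.beta[1])),
            "converged": fit.converged,
        },
    )
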