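"""Parametric survival curves, hazard-ratio adjustment and model fitting.

Lifetime extrapolation of progression-free and overall survival uses the
Weibull form S(t) = exp(-scale * t**shape) with time in months.  Comparator
arms share the reference shape; their scale is the reference scale times the
arm's hazard ratio, which is exactly proportional hazards when the shape is
shared.  Right-censored maximum-likelihood fitting of the five standard
families (exponential, Weibull, Gompertz, log-logistic, log-normal) is
delegated to lifelines, with a Gompertz fitter defined here since lifelines
does not ship one; model selection minimises BIC with AIC as tie-break.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import (
    ExponentialFitter,
    LogLogisticFitter,
    LogNormalFitter,
    WeibullFitter,
)
from lifelines.fitters import ParametricUnivariateFitter
from scipy.special import gamma as gamma_fn

from .params import WEEKS_PER_YEAR, LifeTable, WeibullParams

__all__ = [
    "SurvivalDataset",
    "FitResult",
    "FAMILY_ORDER",
    "weibull_survival",
    "weibull_median",
    "weibull_mean",
    "apply_hazard_ratio",
    "cycle_transition_probability",
    "fit_parametric",
    "select_model",
    "weekly_background_mortality",
]

#: family order as conventionally listed; used as the final tie-break
FAMILY_ORDER = ("exponential", "weibull", "gompertz", "loglogistic", "lognormal")


@dataclass
class SurvivalDataset:
    """Right-censored time-to-event data (times in months, event=1/censored=0)."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape or self.times.ndim != 1:
            raise ValueError("times and events must be matching 1-d arrays")
        if np.any(self.times <= 0):
            raise ValueError("event/censoring times must be positive")
        if not np.all(np.isin(self.events, (0, 1))):
            raise ValueError("events must be 0 or 1")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @classmethod
    def from_csv(cls, path: str | Path) -> "SurvivalDataset":
        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["event"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_months": self.times, "event": self.events}).to_csv(
            path, index=False
        )


@dataclass
class FitResult:
    """A fitted parametric survival model with information criteria."""

    family: str
    params: dict[str, float]
    loglik: float
    aic: float
    bic: float
    n: int
    n_events: int


# --------------------------------------------------------------------------
# Weibull curve operations
# --------------------------------------------------------------------------


def weibull_survival(params: WeibullParams, t) -> float | np.ndarray:
    """S(t) = exp(-scale * t**shape); t in months, scalar or array."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = np.exp(-params.scale * t**params.shape)
    return float(out) if out.ndim == 0 else out


def weibull_median(params: WeibullParams) -> float:
    return (math.log(2.0) / params.scale) ** (1.0 / params.shape)


def weibull_mean(params: WeibullParams) -> float:
    """Mean survival time (months): (1/scale)^(1/shape) * Gamma(1 + 1/shape)."""
    return (1.0 / params.scale) ** (1.0 / params.shape) * float(
        gamma_fn(1.0 + 1.0 / params.shape)
    )


def apply_hazard_ratio(ref: WeibullParams, hr: float) -> WeibullParams:
    """Scale the reference hazard by ``hr`` (shared shape -> exact PH)."""
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    return WeibullParams(
        scale=ref.scale * hr,
        shape=ref.shape,
        log_chol=None if ref.log_chol is None else ref.log_chol.copy(),
        scale_range=ref.scale_range,
        shape_range=ref.shape_range,
    )


def cycle_transition_probability(
    params: WeibullParams, cycle_index: int, cycle_length: float
) -> float:
    """Probability of the event during cycle ``cycle_index``, conditional on
    being event-free at its start: 1 - S(t_{k+1})/S(t_k), t_k = k*cycle_length.

    Computed as 1 - exp(-scale*(t1^shape - t0^shape)), which is exact and
    avoids underflow of S at late cycles.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if cycle_length <= 0:
        raise ValueError("cycle_length must be positive")
    t0 = cycle_index * cycle_length
    t1 = (cycle_index + 1) * cycle_length
    return float(
        -math.expm1(-params.scale * (t1**params.shape - t0**params.shape))
    )


def weekly_background_mortality(table: LifeTable, age: float) -> float:
    """Convert the annual all-cause mortality at ``age`` to a weekly probability."""
    q = table.annual_q(age)
    return 1.0 - (1.0 - q) ** (1.0 / WEEKS_PER_YEAR)


# --------------------------------------------------------------------------
# maximum-likelihood fitting
# --------------------------------------------------------------------------


class GompertzFitter(ParametricUnivariateFitter):
    """Gompertz model with hazard h(t) = a * exp(b*t).

    Cumulative hazard H(t) = (a/b) * (exp(b*t) - 1).  lifelines has no
    built-in Gompertz fitter, so one is defined via its parametric-fitter
    machinery.
    """

    _fitted_parameter_names = ["a_", "b_"]
    _bounds = [(1e-12, None), (1e-12, None)]

    def _cumulative_hazard(self, params, times):
        a, b = params
        return (a / b) * np.expm1(b * times)


def _weibull_native_params(fitter: WeibullFitter) -> dict[str, float]:
    # lifelines: S(t) = exp(-(t/lambda_)^rho_)  ->  scale = lambda_^(-rho_)
    lam, rho = float(fitter.lambda_), float(fitter.rho_)
    return {"scale": lam ** (-rho), "shape": rho, "lifelines_lambda": lam}


_FITTERS = {
    "exponential": ExponentialFitter,
    "weibull": WeibullFitter,
    "gompertz": GompertzFitter,
    "loglogistic": LogLogisticFitter,
    "lognormal": LogNormalFitter,
}


def fit_parametric(data: SurvivalDataset, family: str) -> FitResult:
    """Fit one parametric family by right-censored maximum likelihood.

    Requires at least 10 observations and at least one event.  Raises
    ``RuntimeError`` carrying the optimizer diagnostics on non-convergence.
    """
    if family not in _FITTERS:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILY_ORDER}")
    if len(data) < 10:
        raise ValueError("need at least 10 observations")
    if data.n_events == 0:
        raise ValueError("all observations censored; cannot fit")
    fitter = _FITTERS[family]()
    try:
        fitter.fit(data.times, event_observed=data.events)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"{family} fit failed to converge: {exc}") from exc

    k = len(fitter._fitted_parameter_names)
    n = len(data)
    loglik = float(fitter.log_likelihood_)
    if family == "weibull":
        params = _weibull_native_params(fitter)
    else:
        params = {
            name: float(getattr(fitter, name))
            for name in fitter._fitted_parameter_names
        }
    if family == "exponential":
        # lifelines parameterizes by mean; also report the hazard rate
        params["rate"] = 1.0 / params["lambda_"]
    return FitResult(
        family=family,
        params=params,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k,
        bic=-2.0 * loglik + k * math.log(n),
        n=n,
        n_events=data.n_events,
    )


def fit_all_families(data: SurvivalDataset) -> list[FitResult]:
    """Fit every family in :data:`FAMILY_ORDER`, skipping non-convergent ones."""
    fits = []
    for family in FAMILY_ORDER:
        try:
            fits.append(fit_parametric(data, family))
        except RuntimeError:
            continue
    if not fits:
        raise RuntimeError("no family converged")
    return fits


def select_model(fits: list[FitResult]) -> FitResult:
    """Best fit by BIC; ties broken by AIC, then by conventional family order."""
    if not fits:
        raise ValueError("no fits supplied")
    return min(fits, key=lambda f: (f.bic, f.aic, FAMILY_ORDER.index(f.family)))
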