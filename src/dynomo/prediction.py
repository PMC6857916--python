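"""Response-scale prediction with confidence intervals.

For a new observation x* the linear predictor is η̂ = x*ᵀβ̂ with standard
error √(x*ᵀ Σ̂ x*).  An approximate 100(1−α)% confidence interval for the
mean response is η̂ ± u_{1−α/2}·se(η̂) computed on the linear scale and
mapped through the inverse link g⁻¹, which keeps the limits inside the
response's natural range (probabilities in [0,1], rates positive).  The
critical value u is a standard-normal quantile for fixed-dispersion
families (binomial, Poisson) and a Student-t quantile on the residual
degrees of freedom when the dispersion is estimated (gaussian, gamma).

Cox models get survival curves S(t|x) = exp(−Λ₀(t)·exp((x−x̄)β)) with
pointwise intervals built on the log-cumulative-hazard scale by the delta
method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import design_row
from .fitting import CoxModel, FittedModel
from .links import LINKS

__all__ = [
    "PredictionResult",
    "SurvivalCurve",
    "linear_predictor",
    "confidence_interval",
    "inverse_link",
    "predict_response",
    "survival_curve",
    "survival_at",
    "ExtrapolationWarning",
]


class ExtrapolationWarning(UserWarning):
    """A covariate value outside the range observed at fit time."""


@dataclass
class PredictionResult:
    inputs: dict
    eta: float
    se_eta: float
    level: float
    response_estimate: float
    response_lower: float
    response_upper: float

    def __post_init__(self):
        if not (
            self.response_lower - 1e-12
            <= self.response_estimate
            <= self.response_upper + 1e-12
        ):
            raise ValueError("interval does not bracket the point estimate")


@dataclass
class SurvivalCurve:
    """Right-continuous step survival function for one covariate profile."""

    times: np.ndarray
    survival: np.ndarray
    at_risk_fraction: np.ndarray
    inputs: dict

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.at_risk_fraction = np.asarray(self.at_risk_fraction, dtype=float)
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival function must be non-increasing")
        if self.survival.size and (self.survival[0] > 1.0 + 1e-12):
            raise ValueError("survival cannot exceed 1")

    def at(self, t: float) -> float:
        """S(t): step-function evaluation (1 before the first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _row_for(model, x_new: dict) -> np.ndarray:
    for name, spec in model.variable_specs.items():
        if name not in x_new:
            raise KeyError(f"no value supplied for model variable {name!r}")
        if spec.role == "covariate":
            v = float(x_new[name])
            if spec.observed_min is not None and not (
                spec.observed_min <= v <= spec.observed_max
            ):
                warnings.warn(
                    f"{name}={v} is outside the observed range "
                    f"[{spec.observed_min}, {spec.observed_max}]; "
                    "prediction is an extrapolation",
                    ExtrapolationWarning,
                    stacklevel=3,
                )
    return design_row(model.formula, model.variable_specs, model.column_labels, x_new)


def linear_predictor(model: FittedModel, x_new: dict) -> tuple[float, float]:
    """η̂ = x*ᵀβ̂ and its standard error √(x*ᵀ Σ̂ x*)."""
    x = _row_for(model, x_new)
    eta = float(x @ model.beta)
    var = float(x @ model.sigma @ x)
    return eta, float(np.sqrt(max(var, 0.0)))


def critical_value(model, level: float) -> float:
    """Quantile used for the interval half-width.

    Normal for binomial/Poisson (dispersion known), Student-t on the
    residual df for gaussian/gamma (dispersion estimated), normal for Cox.
    """
    if not 0.0 <= level < 1.0:
        raise ValueError(f"confidence level must be in [0, 1), got {level}")
    q = 1.0 - (1.0 - level) / 2.0
    if getattr(model, "family", None) in ("gaussian", "gamma"):
        return float(stats.t.ppf(q, model.df_residual))
    return float(stats.norm.ppf(q))


def confidence_interval(eta: float, se_eta: float, level: float,
                        model) -> tuple[float, float]:
    """Interval for the mean response on the linear-predictor scale."""
    u = critical_value(model, level)
    return eta - u * se_eta, eta + u * se_eta


def inverse_link(family: str, link: str, eta_values):
    """Map linear-predictor values to the response scale via g⁻¹.

    For the (decreasing) reciprocal link an interval that spans zero has
    no defined mean-response image and raises.
    """
    lk = LINKS[link]
    eta_arr = np.atleast_1d(np.asarray(eta_values, dtype=float))
    if lk.name == "reciprocal" and eta_arr.min() <= 0.0 <= eta_arr.max():
        raise ValueError(
            "reciprocal link: linear-predictor interval spans 0, the mean "
            "response is undefined there"
        )
    out = lk.inverse(np.asarray(eta_values, dtype=float))
    return out


def predict_response(model: FittedModel, x_new: dict,
                     level: float = 0.95) -> PredictionResult:
    """Point estimate and CI for the mean response at ``x_new``."""
    eta, se = linear_predictor(model, x_new)
    lo, hi = confidence_interval(eta, se, level, model)
    est = float(inverse_link(model.family, model.link, eta))
    a = float(inverse_link(model.family, model.link, lo))
    b = float(inverse_link(model.family, model.link, hi))
    lo_r, hi_r = (b, a) if LINKS[model.link].decreasing else (a, b)
    return PredictionResult(
        inputs=dict(x_new), eta=eta, se_eta=se, level=level,
        response_estimate=est, response_lower=lo_r, response_upper=hi_r,
    )


# --------------------------------------------------------------------------
# Cox


def _cox_eta(cox: CoxModel, x_new: dict) -> tuple[np.ndarray, float]:
    x = _row_for(cox, x_new)
    xc = x - cox.covariate_means
    return xc, float(xc @ cox.beta)


def survival_curve(cox: CoxModel, x_new: dict) -> SurvivalCurve:
    """S(t|x) as a right-continuous step function at the event times.

    ``at_risk_fraction`` (at-risk count / n) rides along for alpha-blended
    display of estimate uncertainty over follow-up.
    """
    _, eta_c = _cox_eta(cox, x_new)
    surv = np.exp(-cox.baseline_cumhaz * np.exp(eta_c))
    return SurvivalCurve(
        times=cox.event_times,
        survival=surv,
        at_risk_fraction=cox.at_risk / cox.n_used,
        inputs=dict(x_new),
    )


def survival_at(cox: CoxModel, x_new: dict, t: float,
                level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Predicted survival at time ``t`` with a delta-method interval.

    The variance of Λ̂(t|x) combines the baseline (Nelson–Aalen-type) term
    Σ_{t_j≤t} d_j/S0_j² scaled by exp(2η) with the coefficient-uncertainty
    term gᵀΣ̂g, where g = ∂Λ̂/∂β.  The interval is symmetric on the
    log-cumulative-hazard scale and back-transformed, so it respects
    [0, 1].
    """
    last = float(np.max(np.concatenate([cox.event_times, [0.0]])))
    if t > last:
        raise ValueError(
            f"t={t} is beyond the last observed event time {last}; "
            "no baseline information there"
        )
    xc, eta_c = _cox_eta(cox, x_new)
    mask = cox.event_times <= t
    # cumulative hazard at t for this profile
    increments = np.diff(np.concatenate([[0.0], cox.baseline_cumhaz]))
    lam0 = float(np.sum(increments[mask]))
    rr = float(np.exp(eta_c))
    lam = lam0 * rr
    point = float(np.exp(-lam))
    if lam <= 0.0:
        return 1.0, (1.0, 1.0)
    # delta-method variance of Λ̂(t|x)
    base_var = float(np.sum(cox.var_increments[mask])) * rr ** 2
    # ∂Λ/∂β = rr·(xc·Λ0 − Σ increments·(S1/S0))
    g = rr * (xc * lam0 - increments[mask] @ cox.s1_over_s0[mask])
    beta_var = float(g @ cox.sigma @ g)
    var_lam = base_var + beta_var
    se_log_lam = np.sqrt(var_lam) / lam
    u = critical_value(cox, level)
    lam_lo = lam * np.exp(-u * se_log_lam)
    lam_hi = lam * np.exp(u * se_log_lam)
    lo = float(np.clip(np.exp(-lam_hi), 0.0, 1.0))
    hi = float(np.clip(np.exp(-lam_lo), 0.0, 1.0))
    return point, (min(lo, point), max(hi, point))
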