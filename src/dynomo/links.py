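"""Link functions and family variance functions for the GLM engine.

Each link supplies g (mean → linear predictor), its inverse g⁻¹, and
dμ/dη, which is all IRLS and response-scale prediction need.  Supported
pairs: gaussian/identity, binomial/logit, poisson/log, gamma/reciprocal
(μ = 1/η) and gamma/log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["Link", "LINKS", "family_variance", "check_response"]


@dataclass(frozen=True)
class Link:
    name: str
    g: Callable[[np.ndarray], np.ndarray]
    inverse: Callable[[np.ndarray], np.ndarray]
    dmu_deta: Callable[[np.ndarray], np.ndarray]
    #: True if g⁻¹ is monotone decreasing (interval limits swap under it)
    decreasing: bool = False


def _logit(mu):
    mu = np.asarray(mu, dtype=float)
    return np.log(mu / (1.0 - mu))


def _expit(eta):
    eta = np.asarray(eta, dtype=float)
    # numerically stable inverse logit
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


LINKS: dict[str, Link] = {
    "identity": Link(
        "identity",
        g=lambda mu: np.asarray(mu, dtype=float),
        inverse=lambda eta: np.asarray(eta, dtype=float),
        dmu_deta=lambda eta: np.ones_like(np.asarray(eta, dtype=float)),
    ),
    "logit": Link(
        "logit",
        g=_logit,
        inverse=_expit,
        dmu_deta=lambda eta: _expit(eta) * (1.0 - _expit(eta)),
    ),
    "log": Link(
        "log",
        g=lambda mu: np.log(np.asarray(mu, dtype=float)),
        inverse=lambda eta: np.exp(np.asarray(eta, dtype=float)),
        dmu_deta=lambda eta: np.exp(np.asarray(eta, dtype=float)),
    ),
    # reciprocal: μ = 1/η (decreasing, so CI limits swap on back-transform)
    "reciprocal": Link(
        "reciprocal",
        g=lambda mu: 1.0 / np.asarray(mu, dtype=float),
        inverse=lambda eta: 1.0 / np.asarray(eta, dtype=float),
        dmu_deta=lambda eta: -1.0 / np.asarray(eta, dtype=float) ** 2,
        decreasing=True,
    ),
}


def family_variance(family: str) -> Callable[[np.ndarray], np.ndarray]:
    """Variance function V(μ) of the exponential family."""
    return {
        "gaussian": lambda mu: np.ones_like(np.asarray(mu, dtype=float)),
        "binomial": lambda mu: mu * (1.0 - mu),
        "poisson": lambda mu: np.asarray(mu, dtype=float),
        "gamma": lambda mu: np.asarray(mu, dtype=float) ** 2,
    }[family]


def check_response(family: str, y: np.ndarray) -> None:
    """Validate that y lies in the family's support."""
    if family == "binomial":
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binomial response must be coded 0/1")
    elif family == "poisson":
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValueError("poisson response must be non-negative integers")
    elif family == "gamma":
        if (y <= 0).any():
            raise ValueError("gamma response must be strictly positive")
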