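"""Model fitting: OLS, iteratively reweighted least squares for GLMs, and
Newton–Raphson Cox partial-likelihood maximization with a Breslow baseline
cumulative hazard.

Estimation conventions
----------------------
* OLS: β̂ = (XᵀX)⁻¹Xᵀy via QR; dispersion = RSS/(n−p); Σ̂ = σ̂²(XᵀX)⁻¹.
* GLM: IRLS to convergence (max|Δβ| < tol); Σ̂ = φ(XᵀWX)⁻¹ with the
  dispersion φ fixed at 1 for binomial/Poisson, RSS/(n−p) for gaussian and
  the Pearson estimate for gamma.
* Cox: partial likelihood with Efron (default) or Breslow tie correction,
  covariates centered at their means; Σ̂ = inverse observed information;
  baseline cumulative hazard by the Breslow estimator on the centered
  scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
from scipy import special

from .design import DesignMatrix, compute_variable_specs, build_design
from .formula import ModelFormula, TermSpec, VariableSpec
from .links import LINKS, check_response, family_variance

__all__ = [
    "FittedModel",
    "CoxModel",
    "fit_ols",
    "fit_glm_irls",
    "fit_cox",
    "fit_model",
    "export_model",
    "import_model",
    "ConvergenceError",
    "SeparationError",
    "RankDeficiencyError",
]


class ConvergenceError(RuntimeError):
    """Iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []


class SeparationError(ConvergenceError):
    """Coefficients diverging — complete or quasi-complete separation."""


class RankDeficiencyError(np.linalg.LinAlgError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear column(s): {self.columns}")


@dataclass
class FittedModel:
    """A fitted linear/generalized-linear model, self-contained for
    prediction and nomogram construction (no reference to training data)."""

    formula: ModelFormula
    beta: np.ndarray
    sigma: np.ndarray
    dispersion: float
    df_residual: int
    n_used: int
    loglik: float
    variable_specs: dict[str, VariableSpec]
    column_labels: list[str]

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        p = len(self.beta)
        if self.sigma.shape != (p, p):
            raise ValueError(
                f"covariance shape {self.sigma.shape} does not match {p} coefficients"
            )
        if len(self.column_labels) != p:
            raise ValueError("column_labels length does not match beta")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("covariance matrix is not symmetric")
        eigmin = float(np.linalg.eigvalsh((self.sigma + self.sigma.T) / 2).min())
        if eigmin < -1e-8 * max(1.0, float(np.abs(self.sigma).max())):
            raise ValueError("covariance matrix is not positive semi-definite")

    @property
    def family(self) -> str:
        return self.formula.family

    @property
    def link(self) -> str | None:
        return self.formula.link

    def coef_table(self) -> dict[str, np.ndarray]:
        se = np.sqrt(np.diag(self.sigma))
        stat = np.divide(self.beta, se, out=np.zeros_like(self.beta), where=se > 0)
        return {"estimate": self.beta, "se": se, "statistic": stat}


@dataclass
class CoxModel:
    """Cox proportional-hazards fit plus Breslow baseline quantities.

    The baseline cumulative hazard Λ₀ is estimated on the centered scale
    (covariates minus their means), so survival for a new subject is
    S(t|x) = exp(−Λ₀(t)·exp((x−x̄)β)).  ``at_risk`` and the variance
    pieces (``var_increments`` = d_j/S0_j², ``s1_over_s0``) are stored per
    distinct event time for downstream interval estimation and
    alpha-blended display.
    """

    formula: ModelFormula
    beta: np.ndarray
    sigma: np.ndarray
    event_times: np.ndarray
    baseline_cumhaz: np.ndarray
    at_risk: np.ndarray
    n_events_at: np.ndarray
    n_events: int
    n_used: int
    loglik: float
    covariate_means: np.ndarray
    variable_specs: dict[str, VariableSpec]
    column_labels: list[str]
    ties: str = "efron"
    var_increments: np.ndarray | None = None
    s1_over_s0: np.ndarray | None = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.baseline_cumhaz = np.asarray(self.baseline_cumhaz, dtype=float)
        self.at_risk = np.asarray(self.at_risk)
        if np.any(np.diff(self.baseline_cumhaz) < 0):
            raise ValueError("baseline cumulative hazard must be non-decreasing")
        if np.any(np.diff(self.at_risk) > 0):
            raise ValueError("at-risk counts must be non-increasing in time")

    @property
    def family(self) -> str:
        return "cox"

    @property
    def dispersion(self) -> float:
        return 1.0

    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)


# --------------------------------------------------------------------------
# least squares


def _solve_weighted_ls(X: np.ndarray, z: np.ndarray, w: np.ndarray,
                       labels) -> tuple[np.ndarray, np.ndarray]:
    """Solve min ||W^{1/2}(z − Xβ)||²; returns β and (XᵀWX)⁻¹."""
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    q, r, piv = scipy.linalg.qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(Xw.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [labels[j] for j in piv[rank:]]
        raise RankDeficiencyError(bad)
    beta = scipy.linalg.solve_triangular(r, q.T @ (z * sw))
    beta[piv] = beta.copy()
    rinv = scipy.linalg.solve_triangular(r, np.eye(r.shape[0]))
    xtwx_inv = rinv @ rinv.T
    # undo the pivoting on both axes
    inv = np.empty_like(xtwx_inv)
    inv[np.ix_(piv, piv)] = xtwx_inv
    return beta, inv


def fit_ols(design: DesignMatrix, y) -> FittedModel:
    """Ordinary least squares with the classical covariance estimate."""
    X = design.matrix
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p for OLS, got n={n}, p={p}")
    beta, xtx_inv = _solve_weighted_ls(X, y, np.ones(n), design.column_labels)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dispersion = rss / (n - p)
    sigma = dispersion * xtx_inv
    loglik = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    return FittedModel(
        formula=design.formula,
        beta=beta,
        sigma=sigma,
        dispersion=dispersion,
        df_residual=n - p,
        n_used=n,
        loglik=loglik,
        variable_specs=getattr(design, "specs", {}),
        column_labels=design.column_labels,
    )


# --------------------------------------------------------------------------
# GLM / IRLS


def _glm_loglik(family: str, y, mu, dispersion: float, n: int) -> float:
    if family == "gaussian":
        rss = float(np.sum((y - mu) ** 2))
        return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    if family == "binomial":
        return float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    if family == "poisson":
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    if family == "gamma":
        shape = 1.0 / dispersion
        return float(
            np.sum(
                shape * np.log(shape * y / mu)
                - shape * y / mu
                - np.log(y)
                - special.gammaln(shape)
            )
        )
    raise ValueError(family)


def glm_score(design: DesignMatrix, y, beta, family: str, link: str) -> np.ndarray:
    """Score vector Xᵀ(y−μ)·g-weight at β (unit dispersion).

    For canonical links this is exactly Xᵀ(y−μ); used by tests to check
    first-order optimality of the IRLS solution.
    """
    X = design.matrix
    lk = LINKS[link]
    eta = X @ np.asarray(beta, dtype=float)
    mu = lk.inverse(eta)
    V = family_variance(family)(mu)
    w = lk.dmu_deta(eta) / V
    return X.T @ ((np.asarray(y, dtype=float) - mu) * w)


def fit_glm_irls(design: DesignMatrix, y, family: str | None = None,
                 link: str | None = None, tol: float = 1e-9,
                 max_iter: int = 50) -> FittedModel:
    """Fit a GLM by iteratively reweighted least squares.

    Starts from β = 0 with the intercept at g(ȳ); iterates weighted least
    squares on the working response until max|Δβ| < ``tol``.  Raises
    :class:`SeparationError` when coefficients diverge (the hallmark of
    complete separation in logistic models) and :class:`ConvergenceError`
    (carrying the per-iteration trace) when ``max_iter`` is exhausted.
    """
    formula = design.formula
    family = family or formula.family
    link = link or formula.link or {"gaussian": "identity"}[family]
    X = design.matrix
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    check_response(family, y)
    lk = LINKS[link]
    Vfun = family_variance(family)

    beta = np.zeros(p)
    if design.has_intercept:
        ybar = float(np.mean(y))
        if family == "binomial":
            ybar = min(max(ybar, 1e-8), 1 - 1e-8)
        elif family in ("poisson", "gamma"):
            ybar = max(ybar, 1e-8)
        beta[0] = float(lk.g(ybar))

    trace = []
    for it in range(max_iter):
        eta = X @ beta
        mu = lk.inverse(eta)
        dmu = lk.dmu_deta(eta)
        V = Vfun(mu)
        w = dmu ** 2 / V
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ConvergenceError(
                f"invalid IRLS weights at iteration {it} (family={family}, link={link})",
                trace,
            )
        z = eta + (y - mu) / dmu
        new_beta, xtwx_inv = _solve_weighted_ls(X, z, w, design.column_labels)
        delta = float(np.max(np.abs(new_beta - beta)))
        trace.append({"iter": it, "beta": new_beta.copy(), "delta": delta})
        beta = new_beta
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e8:
            raise SeparationError(
                "coefficients diverging — data may be separated "
                f"(max|beta| = {np.max(np.abs(beta)):.3g})",
                trace,
            )
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(last max|Δbeta| = {trace[-1]['delta']:.3g})",
            trace,
        )

    eta = X @ beta
    mu = lk.inverse(eta)
    if family in ("binomial", "poisson"):
        dispersion = 1.0
    elif family == "gaussian":
        dispersion = float(np.sum((y - mu) ** 2)) / (n - p)
    else:  # gamma: Pearson estimate
        dispersion = float(np.sum(((y - mu) / mu) ** 2)) / (n - p)
    sigma = dispersion * xtwx_inv
    loglik = _glm_loglik(family, y, mu, dispersion, n)
    return FittedModel(
        formula=formula,
        beta=beta,
        sigma=sigma,
        dispersion=dispersion,
        df_residual=n - p,
        n_used=n,
        loglik=loglik,
        variable_specs=getattr(design, "specs", {}),
        column_labels=design.column_labels,
    )


# --------------------------------------------------------------------------
# Cox proportional hazards


def cox_partial_loglik(Xc: np.ndarray, time, status, beta,
                       ties: str = "efron") -> float:
    """Partial log-likelihood at β (covariates already centered).

    Written-out form used both by the Newton solver and by brute-force
    grid-search oracles in the tests.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = Xc @ beta
    ll, _, _ = _cox_ll_grad_hess(Xc, np.asarray(time, float),
                                 np.asarray(status), eta, ties, want_derivs=False)
    return ll


def _cox_ll_grad_hess(Xc, time, status, eta, ties, want_derivs=True):
    exp_eta = np.exp(eta)
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    event_times = np.unique(t_sorted[status[order] == 1])
    if len(event_times) == int(status.sum()):
        # no tied events: Efron == Breslow; use suffix cumulative sums
        return _cox_ll_grad_hess_nz(Xc, time, status, exp_eta, order, want_derivs)
    p = Xc.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for tj in event_times:
        risk = time >= tj
        dead = (time == tj) & (status == 1)
        d = int(dead.sum())
        s0 = float(exp_eta[risk].sum())
        ll += float(eta[dead].sum())
        if want_derivs:
            s1 = Xc[risk].T @ exp_eta[risk]
            s2 = (Xc[risk] * exp_eta[risk, None]).T @ Xc[risk]
            grad += Xc[dead].sum(axis=0)
        if ties == "breslow":
            ll -= d * np.log(s0)
            if want_derivs:
                grad -= d * s1 / s0
                hess -= d * (s2 / s0 - np.outer(s1, s1) / s0 ** 2)
        else:  # efron
            s0d = float(exp_eta[dead].sum())
            if want_derivs:
                s1d = Xc[dead].T @ exp_eta[dead]
                s2d = (Xc[dead] * exp_eta[dead, None]).T @ Xc[dead]
            for l in range(d):
                c = l / d
                denom = s0 - c * s0d
                ll -= np.log(denom)
                if want_derivs:
                    num1 = s1 - c * s1d
                    num2 = s2 - c * s2d
                    grad -= num1 / denom
                    hess -= num2 / denom - np.outer(num1, num1) / denom ** 2
    return ll, grad, hess


def _cox_ll_grad_hess_nz(Xc, time, status, exp_eta, order, want_derivs):
    """Untied-events partial likelihood via suffix sums (O(n p²))."""
    n, p = Xc.shape
    t_s = time[order]
    st_s = status[order]
    X_s = Xc[order]
    w_s = exp_eta[order]
    s0 = np.cumsum(w_s[::-1])[::-1]
    # risk set at t_j includes every subject with time >= t_j; with ties in
    # observation times the suffix must start at the first index of the tie
    first_idx = np.searchsorted(t_s, t_s, side="left")
    ev = np.flatnonzero(st_s == 1)
    ridx = first_idx[ev]
    eta_s = np.log(w_s)
    ll = float(eta_s[ev].sum() - np.log(s0[ridx]).sum())
    if not want_derivs:
        return ll, np.zeros(p), np.zeros((p, p))
    s1 = np.cumsum((X_s * w_s[:, None])[::-1], axis=0)[::-1]
    s2 = np.cumsum((X_s[:, :, None] * X_s[:, None, :] * w_s[:, None, None])[::-1],
                   axis=0)[::-1]
    s0e = s0[ridx][:, None]
    m1 = s1[ridx] / s0e
    grad = X_s[ev].sum(axis=0) - m1.sum(axis=0)
    hess = -(s2[ridx] / s0e[:, :, None]).sum(axis=0) + np.einsum("ji,jk->ik", m1, m1)
    return ll, grad, hess


def fit_cox(design: DesignMatrix, time, status, ties: str = "efron",
            tol: float = 1e-9, max_iter: int = 50) -> CoxModel:
    """Newton–Raphson Cox fit (no intercept) with step-halving.

    ``status`` is 1 for an observed event, 0 for right-censoring.  The
    covariance is the inverse observed information at β̂; the baseline
    cumulative hazard (Breslow estimator) and the at-risk counts at each
    distinct event time are attached to the returned model.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    if design.has_intercept:
        raise ValueError("Cox design must not contain an intercept column")
    X = design.matrix
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    if not np.isin(status, (0, 1)).all():
        raise ValueError("status must be coded 0/1")
    status = status.astype(int)
    if (time <= 0).any():
        raise ValueError("event/censoring times must be positive")
    if status.sum() == 0:
        raise ValueError("no events (status == 1) in the data")

    means = X.mean(axis=0)
    Xc = X - means
    n, p = X.shape
    beta = np.zeros(p)
    ll, grad, hess = _cox_ll_grad_hess(Xc, time, status, Xc @ beta, ties)
    trace = []
    for it in range(max_iter):
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix at iteration {it}", trace) from exc
        # step-halving keeps the partial likelihood monotone
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            new_ll, new_grad, new_hess = _cox_ll_grad_hess(Xc, time, status, Xc @ cand, ties)
            if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                break
            factor /= 2.0
        delta = float(np.max(np.abs(cand - beta)))
        beta, ll, grad, hess = cand, new_ll, new_grad, new_hess
        trace.append({"iter": it, "beta": beta.copy(), "loglik": ll, "delta": delta})
        if np.max(np.abs(beta)) > 1e3 * max(1.0, 1.0 / max(Xc.std(axis=0).min(), 1e-12)):
            raise SeparationError(
                "Cox coefficients diverging — a covariate may perfectly rank the events",
                trace,
            )
        if delta < tol:
            break
    else:
        raise ConvergenceError(f"Cox fit did not converge in {max_iter} iterations", trace)

    sigma = np.linalg.inv(-hess)
    base = _breslow_baseline_arrays(Xc, time, status, beta)
    return CoxModel(
        formula=design.formula,
        beta=beta,
        sigma=sigma,
        event_times=base["times"],
        baseline_cumhaz=base["cumhaz"],
        at_risk=base["at_risk"],
        n_events_at=base["d"],
        n_events=int(status.sum()),
        n_used=n,
        loglik=ll,
        covariate_means=means,
        variable_specs=getattr(design, "specs", {}),
        column_labels=design.column_labels,
        ties=ties,
        var_increments=base["var_increments"],
        s1_over_s0=base["s1_over_s0"],
    )


def _breslow_baseline_arrays(Xc, time, status, beta) -> dict:
    """Breslow baseline increments dΛ₀(t_j) = d_j / Σ_{risk} exp(η) on the
    centered scale, plus the S1/S0 terms needed for delta-method variances."""
    eta = Xc @ beta
    exp_eta = np.exp(eta)
    event_times = np.unique(time[status == 1])
    d = np.zeros(len(event_times))
    at_risk = np.zeros(len(event_times), dtype=int)
    increments = np.zeros(len(event_times))
    var_inc = np.zeros(len(event_times))
    s1_over_s0 = np.zeros((len(event_times), Xc.shape[1]))
    for j, tj in enumerate(event_times):
        risk = time >= tj
        dj = int(((time == tj) & (status == 1)).sum())
        s0 = float(exp_eta[risk].sum())
        s1 = Xc[risk].T @ exp_eta[risk]
        d[j] = dj
        at_risk[j] = int(risk.sum())
        increments[j] = dj / s0
        var_inc[j] = dj / s0 ** 2
        s1_over_s0[j] = s1 / s0
    return {
        "times": event_times,
        "d": d,
        "at_risk": at_risk,
        "cumhaz": np.cumsum(increments),
        "var_increments": var_inc,
        "s1_over_s0": s1_over_s0,
    }


def breslow_baseline(model: CoxModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(event_times, baseline cumulative hazard, at-risk counts)."""
    return model.event_times, model.baseline_cumhaz, model.at_risk


# --------------------------------------------------------------------------
# convenience + serialization


def fit_model(data, formula: ModelFormula,
              specs: dict[str, VariableSpec] | None = None,
              ties: str = "efron"):
    """Build the design matrix and dispatch to the right fitter."""
    dm = build_design(data, formula, specs=specs)
    rows = data.loc[dm.data_index]
    if formula.family == "cox":
        return fit_cox(dm, rows[formula.time].to_numpy(float),
                       rows[formula.status].to_numpy(), ties=ties)
    y = rows[formula.response].to_numpy(float)
    if formula.family == "gaussian" and formula.link == "identity":
        return fit_ols(dm, y)
    return fit_glm_irls(dm, y)


def _formula_to_dict(f: ModelFormula) -> dict:
    return {
        "response": f.response,
        "family": f.family,
        "link": f.link,
        "time": f.time,
        "status": f.status,
        "terms": [
            {
                "kind": t.kind,
                "variables": list(t.variables),
                "spline_knots": list(t.spline_knots),
                "spline_df": t.spline_df,
            }
            for t in f.terms
        ],
    }


def _formula_from_dict(d: dict) -> ModelFormula:
    terms = [
        TermSpec(
            kind=t["kind"],
            variables=tuple(t["variables"]),
            spline_knots=tuple(t.get("spline_knots", ())),
            spline_df=t.get("spline_df"),
        )
        for t in d["terms"]
    ]
    return ModelFormula(
        response=d.get("response"), family=d["family"], link=d.get("link"),
        terms=terms, time=d.get("time"), status=d.get("status"),
    )


def _specs_to_dict(specs: dict[str, VariableSpec]) -> dict:
    return {
        name: {
            "name": s.name,
            "role": s.role,
            "levels": list(s.levels),
            "observed_min": s.observed_min,
            "observed_max": s.observed_max,
            "mean": s.mean,
            "mode": s.mode,
        }
        for name, s in specs.items()
    }


def _specs_from_dict(d: dict) -> dict[str, VariableSpec]:
    return {name: VariableSpec(**kw) for name, kw in d.items()}


def export_model(model, path=None) -> dict:
    """Serialize a fitted model to the documented JSON schema.

    The payload is everything prediction and layout need — coefficients,
    covariance, dispersion, variable metadata and (for Cox) the baseline —
    with no reference to the training data.
    """
    doc = {
        "format": "dynomo-model",
        "version": 1,
        "family": model.family,
        "columns": list(model.column_labels),
        "beta": model.beta.tolist(),
        "sigma": model.sigma.tolist(),
        "formula": _formula_to_dict(model.formula),
        "variable_specs": _specs_to_dict(model.variable_specs),
        "n_used": model.n_used,
        "loglik": model.loglik,
    }
    if isinstance(model, CoxModel):
        doc["baseline"] = {
            "event_times": model.event_times.tolist(),
            "cumhaz": model.baseline_cumhaz.tolist(),
            "at_risk": model.at_risk.tolist(),
            "n_events_at": model.n_events_at.tolist(),
            "var_increments": model.var_increments.tolist(),
            "s1_over_s0": model.s1_over_s0.tolist(),
            "covariate_means": model.covariate_means.tolist(),
            "ties": model.ties,
            "n_events": model.n_events,
        }
    else:
        doc["link"] = model.link
        doc["dispersion"] = model.dispersion
        doc["df_residual"] = model.df_residual
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
    return doc


def import_model(doc) -> "FittedModel | CoxModel":
    """Inverse of :func:`export_model`; accepts a dict, JSON text or path.

    Dimensional consistency (β vs Σ vs columns) and covariance symmetry
    are validated; an externally produced file with matching schema is
    accepted, which lets models fitted elsewhere be visualised.
    """
    if isinstance(doc, (str, Path)):
        p = Path(doc)
        doc = json.loads(p.read_text() if p.exists() else str(doc))
    beta = np.asarray(doc["beta"], dtype=float)
    sigma = np.asarray(doc["sigma"], dtype=float)
    columns = list(doc["columns"])
    if sigma.shape != (len(beta), len(beta)) or len(columns) != len(beta):
        raise ValueError(
            f"dimension mismatch: {len(beta)} coefficients, covariance "
            f"{sigma.shape}, {len(columns)} columns"
        )
    formula = _formula_from_dict(doc["formula"])
    specs = _specs_from_dict(doc["variable_specs"])
    if doc["family"] == "cox":
        b = doc["baseline"]
        return CoxModel(
            formula=formula, beta=beta, sigma=sigma,
            event_times=np.asarray(b["event_times"], float),
            baseline_cumhaz=np.asarray(b["cumhaz"], float),
            at_risk=np.asarray(b["at_risk"]),
            n_events_at=np.asarray(b["n_events_at"], float),
            n_events=int(b["n_events"]),
            n_used=int(doc["n_used"]),
            loglik=float(doc["loglik"]),
            covariate_means=np.asarray(b["covariate_means"], float),
            variable_specs=specs,
            column_labels=columns,
            ties=b.get("ties", "efron"),
            var_increments=np.asarray(b["var_increments"], float),
            s1_over_s0=np.asarray(b["s1_over_s0"], float),
        )
    return FittedModel(
        formula=formula, beta=beta, sigma=sigma,
        dispersion=float(doc["dispersion"]),
        df_residual=int(doc["df_residual"]),
        n_used=int(doc["n_used"]),
        loglik=float(doc["loglik"]),
        variable_specs=specs,
        column_labels=columns,
    )
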