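"""Static nomogram geometry.

Each model term gets a points ruler.  A term's contribution to the linear
predictor over its observed support (covariate range, factor levels, a
dense grid for splines) has a span max−min; spans are rescaled so the
largest span maps to exactly 100 points.  The classical ruler-length rule
for a linear covariate — range(X)·|β| divided by the largest such product —
is the special case of this span for a term that is linear in one
variable; the span generalizes it to factors, splines and interactions.

Reading a nomogram: locate each predictor value on its ruler, add up the
points, and carry the total through the total-points axis to the response
axis, which inverts total points → linear predictor → g⁻¹ (for Cox models
the final scale is the relative hazard exp((x−x̄)β)).

Interactions between a covariate and factors are drawn as one covariate
ruler per factor-level combination (stratified axes); a covariate×covariate
interaction has no faithful one-dimensional ruler and is refused — the
dynamic interface handles those models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.ticker import MaxNLocator

from .design import rcs_basis, encode_factor
from .fitting import CoxModel, FittedModel
from .formula import TermSpec
from .links import LINKS

__all__ = [
    "AxisSpec",
    "NomogramLayout",
    "term_contribution",
    "ruler_length",
    "build_layout",
    "LayoutUnsupportedError",
]

_GRID = 100  # evaluation grid points for spline / stratified rulers


class LayoutUnsupportedError(ValueError):
    """Model structure with no faithful static ruler representation."""


@dataclass
class AxisSpec:
    """One points ruler: tick positions (value/level → points)."""

    term_names: tuple[str, ...]
    variable: str | None
    ticks: list[tuple[str, float]]
    stratum: str | None = None
    contribution_fn_grid: list[tuple[float, float]] | None = None

    @property
    def max_points(self) -> float:
        return max(p for _, p in self.ticks)


@dataclass
class NomogramLayout:
    axes: list[AxisSpec]
    points_per_unit_eta: float
    total_points_range: tuple[float, float]
    response_ticks: list[tuple[float, float]]
    eta_at_zero_points: float
    response_label: str


def _term_column_labels(model, term: TermSpec) -> list[str]:
    """Labels of the design columns a term produced (deterministic rebuild)."""
    specs = model.variable_specs

    def main_labels(t: TermSpec) -> list[str]:
        if t.kind == "covariate":
            return [t.variables[0]]
        if t.kind == "factor":
            return [f"{t.variables[0]}({lev})" for lev in specs[t.variables[0]].levels[1:]]
        if t.kind == "spline":
            var = t.variables[0]
            k = len(t.spline_knots)
            return [var] + [var + "'" * (j + 1) for j in range(k - 2)]
        raise ValueError(t.kind)

    if term.kind != "interaction":
        return main_labels(term)
    mains = {
        t.variables[0]: main_labels(t)
        for t in model.formula.terms
        if t.kind != "interaction"
    }
    labs = mains[term.variables[0]]
    for v in term.variables[1:]:
        labs = [f"{a}:{b}" for a in labs for b in mains[v]]
    return labs


def _term_beta(model, term: TermSpec) -> np.ndarray:
    labels = _term_column_labels(model, term)
    idx = [model.column_labels.index(l) for l in labels]
    return model.beta[idx]


def _column_values(model, term: TermSpec, values: dict) -> np.ndarray:
    """Design-column values of one term for a single input profile."""
    specs = model.variable_specs

    def main_vals(t: TermSpec) -> np.ndarray:
        var = t.variables[0]
        if t.kind == "covariate":
            return np.array([float(values[var])])
        if t.kind == "factor":
            cols, _ = encode_factor([values[var]], specs[var])
            return cols[0]
        if t.kind == "spline":
            return rcs_basis([float(values[var])], t.spline_knots)[0]
        raise ValueError(t.kind)

    if term.kind != "interaction":
        return main_vals(term)
    mains = {
        t.variables[0]: t for t in model.formula.terms if t.kind != "interaction"
    }
    out = main_vals(mains[term.variables[0]])
    for v in term.variables[1:]:
        out = np.outer(out, main_vals(mains[v])).ravel()
    return out


def term_contribution(model, term: TermSpec, value) -> float:
    """Contribution of one term to η at the given value(s).

    ``value`` is a scalar for covariate/spline terms, a level label for a
    factor, and a dict ``{variable: value}`` for interactions.
    """
    if term.kind == "interaction":
        values = dict(value)
    else:
        values = {term.variables[0]: value}
    cols = _column_values(model, term, values)
    return float(cols @ _term_beta(model, term))


def _support_values(model, var: str) -> list:
    spec = model.variable_specs[var]
    if spec.role == "factor":
        return list(spec.levels)
    return list(np.linspace(spec.observed_min, spec.observed_max, _GRID))


def _term_span(model, term: TermSpec) -> tuple[float, float]:
    """(min, max) of a term's contribution over the observed support."""
    if term.kind == "factor":
        vals = [term_contribution(model, term, l) for l in _support_values(model, term.variables[0])]
    elif term.kind in ("covariate", "spline"):
        spec = model.variable_specs[term.variables[0]]
        if term.kind == "covariate":
            xs = [spec.observed_min, spec.observed_max]
        else:
            xs = _support_values(model, term.variables[0])
        vals = [term_contribution(model, term, x) for x in xs]
    else:  # interaction: grid over the product support
        grids = [_support_values(model, v) for v in term.variables]
        import itertools

        vals = [
            term_contribution(model, term, dict(zip(term.variables, combo)))
            for combo in itertools.product(*grids)
        ]
    return float(min(vals)), float(max(vals))


def ruler_length(model, term: TermSpec) -> float:
    """Relative ruler length in (0, 1]: term span / largest term span."""
    spans = {t.name: np.diff(_term_span(model, t))[0] for t in model.formula.terms}
    largest = max(spans.values())
    if largest == 0:
        raise LayoutUnsupportedError("all terms have zero contribution span")
    mine = spans[term.name]
    if mine == 0:
        warnings.warn(
            f"term {term.name!r} has zero contribution span (beta = 0); "
            "its ruler has length 0",
            stacklevel=2,
        )
    return float(mine / largest)


# --------------------------------------------------------------------------
# axis grouping


def _axis_groups(model) -> list[dict]:
    """Partition terms into axis groups (see module docstring)."""
    specs = model.variable_specs
    groups: dict[tuple, dict] = {}
    for term in model.formula.terms:
        covs = [v for v in term.variables if specs[v].role == "covariate"]
        facs = [v for v in term.variables if specs[v].role == "factor"]
        if len(covs) > 1:
            raise LayoutUnsupportedError(
                f"interaction {term.name!r} involves two covariates; a static "
                "ruler cannot represent it — use the dynamic interface"
            )
        key = ("cov", covs[0]) if covs else ("fac", tuple(sorted(term.variables)))
        g = groups.setdefault(key, {"key": key, "terms": [], "strata_vars": []})
        g["terms"].append(term)
        for f in facs:
            if covs and f not in g["strata_vars"]:
                g["strata_vars"].append(f)
    return list(groups.values())


def _group_contribution(model, group, values: dict) -> float:
    total = 0.0
    for term in group["terms"]:
        if term.kind == "interaction":
            total += term_contribution(
                model, term, {v: values[v] for v in term.variables}
            )
        else:
            total += term_contribution(model, term, values[term.variables[0]])
    return total


def _group_profiles(model, group):
    """Iterate (stratum_label, fixed_levels) for a group's axes."""
    import itertools

    if not group["strata_vars"]:
        yield None, {}
        return
    level_sets = [model.variable_specs[v].levels for v in group["strata_vars"]]
    for combo in itertools.product(*level_sets):
        label = ", ".join(f"{v}={l}" for v, l in zip(group["strata_vars"], combo))
        yield label, dict(zip(group["strata_vars"], combo))


def _nice_ticks(lo: float, hi: float, n: int = 6,
                include_ends: bool = False) -> list[float]:
    ticks = MaxNLocator(nbins=n).tick_values(lo, hi)
    ticks = [float(t) for t in ticks if lo - 1e-9 <= t <= hi + 1e-9]
    if include_ends:
        # endpoint ticks guarantee the ruler spans its full contribution
        tol = 1e-9 * max(hi - lo, 1.0)
        ticks = [t for t in ticks if abs(t - lo) > tol and abs(t - hi) > tol]
        ticks = [lo] + ticks + [hi]
    if not ticks:
        ticks = [lo, hi]
    return ticks


def build_layout(model) -> NomogramLayout:
    """Construct the full nomogram geometry for a fitted model.

    The sum of per-axis points at any input profile, pushed through the
    total-points → response mapping, reproduces ``predict_response`` (or
    the relative hazard for Cox models) — the defining consistency of a
    nomogram.
    """
    groups = _axis_groups(model)

    # span of each group over support × strata
    for g in groups:
        lo, hi = np.inf, -np.inf
        is_factor_group = g["key"][0] == "fac"
        var = None if is_factor_group else g["key"][1]
        for _, fixed in _group_profiles(model, g):
            if is_factor_group:
                import itertools

                level_sets = [model.variable_specs[v].levels for v in g["key"][1]]
                for combo in itertools.product(*level_sets):
                    c = _group_contribution(
                        model, g, dict(zip(g["key"][1], combo))
                    )
                    lo, hi = min(lo, c), max(hi, c)
            else:
                for x in _support_values(model, var):
                    c = _group_contribution(model, g, {var: x, **fixed})
                    lo, hi = min(lo, c), max(hi, c)
        g["min"], g["max"] = float(lo), float(hi)

    max_span = max(g["max"] - g["min"] for g in groups)
    if max_span <= 0:
        raise LayoutUnsupportedError("no term has a positive contribution span")
    scale = 100.0 / max_span

    axes: list[AxisSpec] = []
    for g in groups:
        names = tuple(t.name for t in g["terms"])
        if g["key"][0] == "fac":
            import itertools

            level_sets = [model.variable_specs[v].levels for v in g["key"][1]]
            ticks = []
            for combo in itertools.product(*level_sets):
                c = _group_contribution(model, g, dict(zip(g["key"][1], combo)))
                ticks.append(("/".join(combo), (c - g["min"]) * scale))
            axes.append(
                AxisSpec(term_names=names, variable=None, ticks=ticks, stratum=None)
            )
        else:
            var = g["key"][1]
            spec = model.variable_specs[var]
            has_spline = any(t.kind == "spline" for t in g["terms"])
            tick_xs = _nice_ticks(spec.observed_min, spec.observed_max,
                                  include_ends=True)
            for label, fixed in _group_profiles(model, g):
                ticks = [
                    (f"{x:g}", (_group_contribution(model, g, {var: x, **fixed}) - g["min"]) * scale)
                    for x in tick_xs
                ]
                grid = None
                if has_spline:
                    grid = [
                        (float(x), (_group_contribution(model, g, {var: x, **fixed}) - g["min"]) * scale)
                        for x in _support_values(model, var)
                    ]
                axes.append(
                    AxisSpec(
                        term_names=names,
                        variable=var,
                        ticks=ticks,
                        stratum=label,
                        contribution_fn_grid=grid,
                    )
                )

    total_max = sum((g["max"] - g["min"]) * scale for g in groups)
    intercept = (
        float(model.beta[model.column_labels.index("(Intercept)")])
        if "(Intercept)" in model.column_labels
        else 0.0
    )
    eta_at_zero = intercept + sum(g["min"] for g in groups)

    is_cox = isinstance(model, CoxModel)
    if is_cox:
        inv = np.exp
        g_fun = np.log
        label = "relative hazard exp((x - xbar) beta)"
    else:
        lk = LINKS[model.link]
        inv, g_fun = lk.inverse, lk.g
        label = f"mean response ({model.family}, {model.link} link)"

    eta_lo, eta_hi = eta_at_zero, eta_at_zero + total_max / scale
    r1, r2 = float(inv(np.asarray(eta_lo))), float(inv(np.asarray(eta_hi)))
    r_lo, r_hi = min(r1, r2), max(r1, r2)
    response_ticks = []
    for r in _nice_ticks(r_lo, r_hi, n=7):
        if not r_lo <= r <= r_hi:
            continue
        try:
            eta_r = float(g_fun(np.asarray(r, dtype=float)))
        except (ZeroDivisionError, FloatingPointError):
            continue
        if not np.isfinite(eta_r):
            continue
        response_ticks.append(((eta_r - eta_at_zero) * scale, float(r)))

    return NomogramLayout(
        axes=axes,
        points_per_unit_eta=scale,
        total_points_range=(0.0, float(total_max)),
        response_ticks=response_ticks,
        eta_at_zero_points=eta_at_zero,
        response_label=label,
    )


def total_points(model, layout: NomogramLayout, values: dict) -> float:
    """Sum of per-axis points for an input profile (reading the nomogram)."""
    scale = layout.points_per_unit_eta
    # Σ group minima is implied by eta_at_zero_points = intercept + Σ min_g
    offset = (layout.eta_at_zero_points
              - (float(model.beta[model.column_labels.index("(Intercept)")])
                 if "(Intercept)" in model.column_labels else 0.0))
    eta_terms = 0.0
    for term in model.formula.terms:
        if term.kind == "interaction":
            eta_terms += term_contribution(
                model, term, {v: values[v] for v in term.variables}
            )
        else:
            eta_terms += term_contribution(model, term, values[term.variables[0]])
    return (eta_terms - offset) * scale


def points_to_response(layout: NomogramLayout, total: float,
                       model) -> float:
    """Map a total-points value to the response scale (the bottom rulers)."""
    eta = layout.eta_at_zero_points + total / layout.points_per_unit_eta
    if isinstance(model, CoxModel):
        return float(np.exp(eta))
    return float(LINKS[model.link].inverse(np.asarray(eta)))
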