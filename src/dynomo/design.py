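"""Design-matrix construction: factor coding, restricted cubic splines,
interactions, and full column-to-term metadata.

The design matrix always carries an intercept as its first column (except
for Cox models, which are fit without one).  Factors use treatment
contrasts with the first level of the variable spec as reference, so a
k-level factor contributes k−1 indicator columns labelled ``var(level)``.
Restricted cubic splines follow the truncated-power parametrization with
quantile knots that is standard in regression-modelling practice, so
coefficients printed for spline terms are directly comparable with the
usual R output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formula import ModelFormula, TermSpec, VariableSpec

__all__ = [
    "DesignMatrix",
    "encode_factor",
    "default_knots",
    "rcs_basis",
    "build_design",
    "compute_variable_specs",
]

log = logging.getLogger(__name__)

#: Quantile probabilities for default knot placement, per knot count.
#: These are the conventional defaults of Harrell's regression-modelling
#: framework; k=5 gives (0.05, 0.275, 0.5, 0.725, 0.95).
KNOT_QUANTILES: dict[int, tuple[float, ...]] = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


class UnknownLevelError(ValueError):
    """A factor value not present in the variable's declared levels."""


@dataclass
class DesignMatrix:
    """n × p numeric design matrix plus column metadata.

    ``column_to_term`` maps every non-intercept column index to the term
    that produced it, so downstream modules (nomogram layout, prediction)
    can slice coefficient vectors per term.
    """

    matrix: np.ndarray
    column_labels: list[str]
    column_to_term: dict[int, TermSpec]
    has_intercept: bool
    formula: ModelFormula | None = None
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def columns_for(self, term: TermSpec) -> list[int]:
        return [j for j, t in self.column_to_term.items() if t is term]


def encode_factor(values, spec: VariableSpec) -> tuple[np.ndarray, list[str]]:
    """Treatment-contrast indicators for a factor.

    Returns ``len(levels) - 1`` binary columns; the first level in
    ``spec.levels`` is the reference and contributes the all-zero row.
    Column labels are ``"var(level)"``.
    """
    values = np.asarray([str(v) for v in values])
    levels = spec.levels
    unknown = set(values) - set(levels)
    if unknown:
        raise UnknownLevelError(
            f"factor {spec.name!r}: unseen level(s) {sorted(unknown)!r}; "
            f"known levels are {list(levels)!r}"
        )
    cols = np.column_stack([(values == lev).astype(float) for lev in levels[1:]])
    labels = [f"{spec.name}({lev})" for lev in levels[1:]]
    return cols, labels


def default_knots(x, k: int) -> np.ndarray:
    """Default spline knots: empirical quantiles of ``x``.

    The probability vector depends on the knot count ``k`` (3–7); for
    k=5 it is (0.05, 0.275, 0.5, 0.725, 0.95).  Knots must come out
    strictly increasing, which requires at least ``k`` distinct values.
    """
    if k not in KNOT_QUANTILES:
        raise ValueError(f"knot count must be in {sorted(KNOT_QUANTILES)}, got {k}")
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(np.unique(x)) < k:
        raise ValueError(
            f"need >= {k} distinct values to place {k} knots, "
            f"got {len(np.unique(x))}"
        )
    knots = np.quantile(x, KNOT_QUANTILES[k])
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            f"default quantile knots are not strictly increasing ({knots}); "
            "data too discrete for this knot count"
        )
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (truncated-power form).

    For knots t₁ < … < t_k the basis has k−1 columns: the first is x
    itself; column j+1 (j = 1..k−2) is

        [(x−t_j)₊³ − (x−t_{k−1})₊³·(t_k−t_j)/(t_k−t_{k−1})
                   + (x−t_k)₊³·(t_{k−1}−t_j)/(t_k−t_{k−1})] / (t_k−t₁)²

    which is cubic between the boundary knots and exactly linear outside
    them.  The (t_k−t₁)² normalization keeps the nonlinear columns on the
    scale of x.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or len(knots) < 3:
        raise ValueError("need >= 3 spline knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError(f"spline knots must be strictly increasing, got {knots}")
    x = np.asarray(x, dtype=float)
    k = len(knots)
    t1, tk, tk1 = knots[0], knots[-1], knots[-2]
    norm = (tk - t1) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        col = (
            cube(x - tj)
            - cube(x - tk1) * (tk - tj) / (tk - tk1)
            + cube(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / norm
        cols.append(col)
    return np.column_stack(cols)


def _spline_labels(term: TermSpec) -> list[str]:
    var = term.variables[0]
    k = len(term.spline_knots)
    return [var] + [var + "'" * (j + 1) for j in range(k - 2)]


def compute_variable_specs(data: pd.DataFrame, formula: ModelFormula,
                           roles: dict[str, str] | None = None,
                           level_orders: dict[str, list[str]] | None = None,
                           ) -> dict[str, VariableSpec]:
    """Freeze per-variable metadata (ranges, levels, mean, mode) from data.

    Factor level order defaults to the lexicographic sort of observed
    labels (first = reference), overridable through ``level_orders``.
    """
    roles = roles or {}
    level_orders = level_orders or {}
    factor_vars = {
        t.variables[0] for t in formula.terms if t.kind == "factor"
    }
    specs: dict[str, VariableSpec] = {}
    for name in formula.variable_names:
        col = data[name]
        role = roles.get(name, "factor" if name in factor_vars else "covariate")
        if role == "factor":
            observed = col.dropna().astype(str)
            levels = level_orders.get(name) or sorted(observed.unique())
            counts = observed.value_counts()
            # most frequent level; ties broken lexicographically
            top = counts[counts == counts.max()].index
            specs[name] = VariableSpec(
                name=name, role="factor", levels=tuple(levels), mode=sorted(top)[0]
            )
        else:
            vals = pd.to_numeric(col, errors="raise").dropna()
            specs[name] = VariableSpec(
                name=name,
                role="covariate",
                observed_min=float(vals.min()),
                observed_max=float(vals.max()),
                mean=float(vals.mean()),
            )
    return specs


def _term_columns(term: TermSpec, data: pd.DataFrame,
                  specs: dict[str, VariableSpec]) -> tuple[np.ndarray, list[str]]:
    """Numeric columns and labels for a single main-effect term."""
    if term.kind == "covariate":
        x = pd.to_numeric(data[term.variables[0]], errors="raise").to_numpy(float)
        return x[:, None], [term.variables[0]]
    if term.kind == "factor":
        return encode_factor(data[term.variables[0]], specs[term.variables[0]])
    if term.kind == "spline":
        x = pd.to_numeric(data[term.variables[0]], errors="raise").to_numpy(float)
        if not term.spline_knots:
            term.spline_knots = tuple(default_knots(x, term.spline_df or 5))
        return rcs_basis(x, term.spline_knots), _spline_labels(term)
    raise ValueError(f"not a main-effect term: {term.kind}")


def build_design(data: pd.DataFrame, formula: ModelFormula,
                 specs: dict[str, VariableSpec] | None = None) -> DesignMatrix:
    """Assemble the design matrix for ``formula`` from a typed table.

    Rows with a missing value in any model variable (including response /
    time / status) are dropped (complete-case analysis); the dropped count
    is logged and recorded on the result.  Interaction columns are
    elementwise products of their constituent main-effect columns.  Spline
    knots not given explicitly are placed at the default quantiles of the
    (complete-case) data and frozen on the term.
    """
    used_vars = list(formula.variable_names)
    all_cols = used_vars + [
        v for v in (formula.response, formula.time, formula.status) if v
    ]
    missing = [c for c in all_cols if c not in data.columns]
    if missing:
        raise KeyError(f"formula variables not in data: {missing}")

    complete = data[all_cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dropping %d row(s) with missing model variables", n_dropped)
    data = data.loc[complete]
    if len(data) == 0:
        raise ValueError("no usable rows after complete-case filtering")

    if specs is None:
        specs = compute_variable_specs(data, formula)
    for name, spec in specs.items():
        if spec.role == "factor":
            observed = set(data[name].astype(str).unique())
            if len(observed) < 2:
                raise ValueError(
                    f"factor {name!r} collapses to a single observed level {observed}"
                )

    cox = formula.family == "cox"
    n = len(data)
    blocks: list[np.ndarray] = [] if cox else [np.ones((n, 1))]
    labels: list[str] = [] if cox else ["(Intercept)"]
    col_to_term: dict[int, TermSpec] = {}
    main_cols: dict[str, tuple[np.ndarray, list[str]]] = {}

    offset = len(labels)
    for term in formula.terms:
        if term.kind == "interaction":
            cols, labs = None, None
            for v in term.variables:
                vc, vl = main_cols[v]
                if cols is None:
                    cols, labs = vc, list(vl)
                else:
                    cols = np.einsum("ni,nj->nij", cols, vc).reshape(n, -1)
                    labs = [f"{a}:{b}" for a in labs for b in vl]
        else:
            cols, labs = _term_columns(term, data, specs)
            main_cols[term.variables[0]] = (cols, labs)
        for j in range(cols.shape[1]):
            col_to_term[offset + j] = term
        blocks.append(cols)
        labels.extend(labs)
        offset += cols.shape[1]

    matrix = np.ascontiguousarray(np.hstack(blocks))
    start = 0 if cox else 1
    spans = matrix[:, start:].max(axis=0) - matrix[:, start:].min(axis=0)
    if np.any(spans == 0):
        dead = [labels[start + j] for j in np.flatnonzero(spans == 0)]
        raise ValueError(f"all-constant non-intercept column(s): {dead}")

    dm = DesignMatrix(
        matrix=matrix,
        column_labels=labels,
        column_to_term=col_to_term,
        has_intercept=not cox,
        formula=formula,
        n_dropped=n_dropped,
    )
    dm.data_index = data.index  # rows that survived complete-case filtering
    dm.specs = specs
    return dm


def design_row(formula: ModelFormula, specs: dict[str, VariableSpec],
               labels_template: list[str],
               x_new: dict[str, object]) -> np.ndarray:
    """Design row for a single new observation (same column order as fit)."""
    df = pd.DataFrame({k: [v] for k, v in x_new.items()}, index=[0])
    dm = _row_design(df, formula, specs)
    if dm.column_labels != labels_template:
        raise ValueError(
            f"design row columns {dm.column_labels} do not match fitted "
            f"columns {labels_template}"
        )
    return dm.matrix[0]


def _row_design(df: pd.DataFrame, formula: ModelFormula,
                specs: dict[str, VariableSpec]) -> DesignMatrix:
    """build_design for prediction rows: no response needed, no constant check."""
    n = len(df)
    cox = formula.family == "cox"
    blocks = [] if cox else [np.ones((n, 1))]
    labels = [] if cox else ["(Intercept)"]
    col_to_term: dict[int, TermSpec] = {}
    main_cols: dict[str, tuple[np.ndarray, list[str]]] = {}
    offset = len(labels)
    for term in formula.terms:
        if term.kind == "interaction":
            cols, labs = None, None
            for v in term.variables:
                vc, vl = main_cols[v]
                if cols is None:
                    cols, labs = vc, list(vl)
                else:
                    cols = np.einsum("ni,nj->nij", cols, vc).reshape(n, -1)
                    labs = [f"{a}:{b}" for a in labs for b in vl]
        else:
            if term.kind == "spline" and not term.spline_knots:
                raise ValueError(f"spline term {term.name!r} has no frozen knots")
            cols, labs = _term_columns(term, df, specs)
            main_cols[term.variables[0]] = (cols, labs)
        for j in range(cols.shape[1]):
            col_to_term[offset + j] = term
        blocks.append(cols)
        labels.extend(labs)
        offset += cols.shape[1]
    return DesignMatrix(
        matrix=np.hstack(blocks),
        column_labels=labels,
        column_to_term=col_to_term,
        has_intercept=not cox,
        formula=formula,
    )
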