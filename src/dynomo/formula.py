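"""Model-specification types: variables, terms, and the model formula.

A :class:`ModelFormula` is the declarative description of a regression
model — the response, the distributional family and link, and an ordered
list of terms (plain covariates, categorical factors, restricted cubic
splines, and interactions).  It is deliberately independent of any data;
:mod:`dynomo.design` turns a formula plus a table into a numeric design
matrix, and :mod:`dynomo.fitting` estimates the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "VariableSpec",
    "TermSpec",
    "ModelFormula",
    "FAMILIES",
    "DEFAULT_LINKS",
    "formula_from_dict",
]

#: Supported distributional families.  ``cox`` is the proportional-hazards
#: model and carries no link.
FAMILIES = ("gaussian", "binomial", "poisson", "gamma", "cox")

#: Canonical link per family: the mean response is g⁻¹(η).
DEFAULT_LINKS = {
    "gaussian": "identity",
    "binomial": "logit",
    "poisson": "log",
    "gamma": "reciprocal",
}

_ALLOWED_LINKS = {
    "gaussian": ("identity",),
    "binomial": ("logit",),
    "poisson": ("log",),
    "gamma": ("reciprocal", "log"),
}


@dataclass
class VariableSpec:
    """Metadata for one model variable, frozen at fit time.

    For covariates the observed range bounds the sliders of the dynamic
    nomogram and the rulers of the static one; the mean is the default
    slider position.  For factors the ordered ``levels`` fix the dummy
    coding (first level = reference) and ``mode`` is the default
    drop-down choice.
    """

    name: str
    role: str  # covariate | factor | time | status
    levels: tuple[str, ...] = ()
    observed_min: float | None = None
    observed_max: float | None = None
    mean: float | None = None
    mode: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("covariate", "factor", "time", "status"):
            raise ValueError(f"unknown role {self.role!r} for variable {self.name!r}")
        self.levels = tuple(str(l) for l in self.levels)
        if self.role == "factor":
            if len(set(self.levels)) < 2:
                raise ValueError(
                    f"factor {self.name!r} needs >= 2 distinct levels, got {self.levels}"
                )
            if self.mode is not None and self.mode not in self.levels:
                raise ValueError(
                    f"mode {self.mode!r} of factor {self.name!r} is not one of its levels"
                )
        if self.role == "covariate" and None not in (
            self.observed_min,
            self.observed_max,
            self.mean,
        ):
            if not (self.observed_min <= self.mean <= self.observed_max):
                raise ValueError(
                    f"covariate {self.name!r}: mean {self.mean} outside observed "
                    f"range [{self.observed_min}, {self.observed_max}]"
                )


@dataclass
class TermSpec:
    """One term of the linear predictor.

    kind:
        ``covariate`` — a single numeric column β·x;
        ``factor`` — treatment-contrast indicators, reference level first;
        ``spline`` — restricted cubic spline basis of one covariate;
        ``interaction`` — elementwise products of 2–3 main-effect terms.
    """

    kind: str
    variables: tuple[str, ...]
    spline_knots: tuple[float, ...] = ()
    spline_df: int | None = None  # requested knot count when knots not given
    order: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("covariate", "factor", "spline", "interaction"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        self.variables = tuple(self.variables)
        if self.kind in ("covariate", "factor", "spline") and len(self.variables) != 1:
            raise ValueError(f"{self.kind} term takes exactly one variable")
        if self.kind == "interaction":
            self.order = len(self.variables)
            if not 2 <= self.order <= 3:
                raise ValueError("interaction order must be 2 or 3")
        if self.spline_knots:
            knots = tuple(float(k) for k in self.spline_knots)
            if any(b <= a for a, b in zip(knots, knots[1:])):
                raise ValueError("spline knots must be strictly increasing")
            if len(knots) < 3:
                raise ValueError("spline needs >= 3 knots")
            self.spline_knots = knots

    @property
    def name(self) -> str:
        if self.kind == "interaction":
            return ":".join(self.variables)
        if self.kind == "spline":
            k = len(self.spline_knots) or self.spline_df
            return f"rcs({self.variables[0]},{k})"
        return self.variables[0]


@dataclass
class ModelFormula:
    """Response + family/link + ordered terms (+ time/status for Cox)."""

    response: str | None
    family: str
    terms: list[TermSpec]
    link: str | None = None
    time: str | None = None
    status: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.family == "cox":
            if self.link is not None:
                raise ValueError("cox model has no link function")
            if not (self.time and self.status):
                raise ValueError("cox formula needs time and status variable names")
        else:
            if self.link is None:
                self.link = DEFAULT_LINKS[self.family]
            if self.link not in _ALLOWED_LINKS[self.family]:
                raise ValueError(
                    f"link {self.link!r} not supported for family {self.family!r}"
                )
            if not self.response:
                raise ValueError("non-cox formula needs a response variable")
        self._check_interaction_mains()

    def _check_interaction_mains(self) -> None:
        main_vars = {
            t.variables[0] for t in self.terms if t.kind in ("covariate", "factor", "spline")
        }
        for t in self.terms:
            if t.kind == "interaction":
                missing = [v for v in t.variables if v not in main_vars]
                if missing:
                    raise ValueError(
                        f"interaction {t.name!r}: main effect(s) {missing} missing "
                        "from the formula"
                    )

    @property
    def variable_names(self) -> list[str]:
        """Distinct model variables, in first-appearance order."""
        seen: dict[str, None] = {}
        for t in self.terms:
            for v in t.variables:
                seen.setdefault(v, None)
        return list(seen)


def formula_from_dict(cfg: Mapping) -> ModelFormula:
    """Build a :class:`ModelFormula` from the config mini-language.

    Example (YAML equivalent)::

        response: sqrtragweed
        family: gaussian
        terms:
          - {kind: factor, var: rain}
          - {kind: covariate, var: temperature}
          - {kind: covariate, var: wind.speed}
          - {kind: spline, var: day.in.seas, k: 5}

    Interactions are given as variable lists::

        - {kind: interaction, vars: [age, pclass]}

    Cox models replace ``response`` with ``time``/``status`` names and use
    ``family: cox``.
    """
    terms: list[TermSpec] = []
    for item in cfg["terms"]:
        kind = item["kind"]
        if kind == "interaction":
            terms.append(TermSpec(kind="interaction", variables=tuple(item["vars"])))
        elif kind == "spline":
            terms.append(
                TermSpec(
                    kind="spline",
                    variables=(item["var"],),
                    spline_knots=tuple(item.get("knots", ())),
                    spline_df=item.get("k"),
                )
            )
        else:
            terms.append(TermSpec(kind=kind, variables=(item["var"],)))
    return ModelFormula(
        response=cfg.get("response"),
        family=cfg["family"],
        link=cfg.get("link"),
        terms=terms,
        time=cfg.get("time"),
        status=cfg.get("status"),
    )
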