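import numpy as np
import pytest

from dynomo.fitting import CoxModel, _breslow_baseline_arrays
from dynomo.formula import ModelFormula, TermSpec, VariableSpec
from dynomo.synthetic import CovariateSim, FactorSim, SyntheticSpec, generate_synthetic


@pytest.fixture(scope="session")
def example_cache(tmp_path_factory):
    return tmp_path_factory.mktemp("examples")


@pytest.fixture(scope="session")
def titanic_bundle(example_cache):
    from dynomo.datasets import fetch_example

    return fetch_example("titanic", cache_dir=example_cache)


@pytest.fixture(scope="session")
def lung_bundle(example_cache):
    from dynomo.datasets import fetch_example

    return fetch_example("lung", cache_dir=example_cache)


def titanic_formula(interactions: int = 0) -> ModelFormula:
    """Passenger-survival logistic model: main effects, or with all
    two-way (interactions=2) / up to three-way (interactions=3) terms."""
    terms = [
        TermSpec("covariate", ("age",)),
        TermSpec("factor", ("pclass",)),
        TermSpec("factor", ("sex",)),
    ]
    if interactions >= 2:
        terms += [
            TermSpec("interaction", ("age", "pclass")),
            TermSpec("interaction", ("age", "sex")),
            TermSpec("interaction", ("pclass", "sex")),
        ]
    if interactions >= 3:
        terms += [TermSpec("interaction", ("age", "pclass", "sex"))]
    return ModelFormula(response="survived", family="binomial", terms=terms)


@pytest.fixture(scope="session")
def three_subject_cox():
    """Hand-checkable null Cox model: events at t=1 and t=2, censoring at
    t=3, beta pinned to 0 with zero coefficient covariance.

    Nelson–Aalen by hand: Λ(1) = 1/3, Λ(2) = 1/3 + 1/2."""
    time = np.array([1.0, 2.0, 3.0])
    status = np.array([1, 1, 0])
    x = np.array([[0.5], [1.0], [1.5]])
    Xc = x - x.mean(axis=0)
    beta = np.zeros(1)
    base = _breslow_baseline_arrays(Xc, time, status, beta)
    formula = ModelFormula(
        response=None, family="cox", time="time", status="status",
        terms=[TermSpec("covariate", ("x",))],
    )
    return CoxModel(
        formula=formula,
        beta=beta,
        sigma=np.zeros((1, 1)),
        event_times=base["times"],
        baseline_cumhaz=base["cumhaz"],
        at_risk=base["at_risk"],
        n_events_at=base["d"],
        n_events=2,
        n_used=3,
        loglik=0.0,
        covariate_means=x.mean(axis=0),
        variable_specs={
            "x": VariableSpec("x", "covariate", observed_min=0.5,
                              observed_max=1.5, mean=1.0)
        },
        column_labels=["x"],
        var_increments=base["var_increments"],
        s1_over_s0=base["s1_over_s0"],
    )


def family_spec(family: str, n: int, seed: int) -> SyntheticSpec:
    """Default generating recipes per family for the recovery/coverage
    suites: one continuous covariate and one binary factor, moderate
    effect sizes."""
    cov = (CovariateSim("x", "uniform", (0.0, 2.0)),)
    fac = (FactorSim("g", ("a", "b")),)
    if family == "gaussian":
        return SyntheticSpec(family, n, beta=(1.0, 0.8, -0.5),
                             covariates=cov, factors=fac, seed=seed)
    if family == "binomial":
        return SyntheticSpec(family, n, beta=(-0.5, 0.9, 0.6),
                             covariates=cov, factors=fac, seed=seed)
    if family == "poisson":
        return SyntheticSpec(family, n, beta=(0.2, 0.5, -0.4),
                             covariates=cov, factors=fac, seed=seed)
    if family == "gamma":
        # reciprocal link: eta = 1/mu must stay positive over the support
        return SyntheticSpec(family, n, beta=(0.8, 0.4, 0.3),
                             covariates=cov, factors=fac, seed=seed)
    if family == "cox":
        return SyntheticSpec(family, n, beta=(0.5, -0.4),
                             covariates=cov, factors=fac, seed=seed)
    raise ValueError(family)


@pytest.fixture
def binomial_bundle():
    return generate_synthetic(family_spec("binomial", 800, seed=42))
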