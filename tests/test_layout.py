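import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pytest

from dynomo.fitting import fit_model, import_model
from dynomo.formula import ModelFormula, TermSpec
from dynomo.layout import (
    LayoutUnsupportedError,
    build_layout,
    points_to_response,
    ruler_length,
    term_contribution,
    total_points,
)
from dynomo.prediction import predict_response
from dynomo.design import rcs_basis
from dynomo.svg import layout_to_dict, render_svg
from dynomo.synthetic import (
    CovariateSim,
    FactorSim,
    SyntheticSpec,
    generate_synthetic,
)

from conftest import family_spec

GOLDEN = Path(__file__).parent / "data" / "golden_nomogram.svg"


def _two_covariate_model(beta=(0.0, 1.0, 0.5), ranges=((0.0, 5.0), (0.0, 4.0))):
    """Gaussian model with hand-set coefficients and observed ranges."""
    doc = {
        "family": "gaussian", "link": "identity",
        "columns": ["(Intercept)", "x1", "x2"],
        "beta": list(beta),
        "sigma": [[0.0] * 3 for _ in range(3)],
        "dispersion": 1.0, "df_residual": 40, "n_used": 43, "loglik": 0.0,
        "formula": {
            "response": "y", "family": "gaussian", "link": "identity",
            "time": None, "status": None,
            "terms": [{"kind": "covariate", "variables": ["x1"],
                       "spline_knots": [], "spline_df": None},
                      {"kind": "covariate", "variables": ["x2"],
                       "spline_knots": [], "spline_df": None}],
        },
        "variable_specs": {
            "x1": {"name": "x1", "role": "covariate", "levels": [],
                   "observed_min": ranges[0][0], "observed_max": ranges[0][1],
                   "mean": sum(ranges[0]) / 2, "mode": None},
            "x2": {"name": "x2", "role": "covariate", "levels": [],
                   "observed_min": ranges[1][0], "observed_max": ranges[1][1],
                   "mean": sum(ranges[1]) / 2, "mode": None},
        },
    }
    return import_model(doc)


class TestTermContribution:
    def test_reference_level_and_zero_covariate(self, binomial_bundle):
        m = fit_model(binomial_bundle.table, binomial_bundle.generating.make_formula())
        t_x, t_g = m.formula.terms
        assert term_contribution(m, t_g, "a") == 0.0
        assert term_contribution(m, t_x, 0.0) == 0.0
        assert term_contribution(m, t_g, "b") == pytest.approx(m.beta[2])

    def test_spline_contribution_matches_basis_dot_product(self):
        rng = np.random.default_rng(5)
        import pandas as pd

        df = pd.DataFrame({"d": rng.uniform(0, 92, 300)})
        df["y"] = np.sin(df.d / 20) + rng.normal(0, 0.1, 300)
        f = ModelFormula(response="y", family="gaussian",
                         terms=[TermSpec("spline", ("d",), spline_df=5)])
        m = fit_model(df, f)
        term = m.formula.terms[0]
        x = 33.3
        basis = rcs_basis(np.array([x]), term.spline_knots)[0]
        expected = float(basis @ m.beta[1:])
        assert term_contribution(m, term, x) == pytest.approx(expected, abs=1e-12)


class TestRulerLength:
    def test_hand_arithmetic(self):
        # spans: |1.0|·5 = 5 and |0.5|·4 = 2 → relative lengths 1 and 0.4
        m = _two_covariate_model()
        t1, t2 = m.formula.terms
        assert ruler_length(m, t1) == 1.0
        assert ruler_length(m, t2) == pytest.approx(0.4)

    def test_zero_span_term_warns_and_has_length_zero(self):
        m = _two_covariate_model(beta=(0.0, 1.0, 0.0))
        with pytest.warns(UserWarning, match="zero contribution span"):
            assert ruler_length(m, m.formula.terms[1]) == 0.0
        assert ruler_length(m, m.formula.terms[0]) == 1.0

    def test_translation_invariance(self):
        a = _two_covariate_model(ranges=((0.0, 5.0), (0.0, 4.0)))
        b = _two_covariate_model(ranges=((100.0, 105.0), (0.0, 4.0)))
        assert ruler_length(a, a.formula.terms[1]) == ruler_length(
            b, b.formula.terms[1]
        )

    def test_max_ruler_length_is_exactly_one(self):
        spec = family_spec("poisson", 300, seed=83)
        bundle = generate_synthetic(spec)
        m = fit_model(bundle.table, spec.make_formula())
        assert max(ruler_length(m, t) for t in m.formula.terms) == 1.0

    def test_covariate_rescaling_leaves_length_unchanged(self):
        spec = family_spec("gaussian", 400, seed=85)
        bundle = generate_synthetic(spec)
        f = spec.make_formula()
        m1 = fit_model(bundle.table, f)
        scaled = bundle.table.copy()
        scaled["x"] = scaled["x"] * 10.0
        m2 = fit_model(scaled, spec.make_formula())
        t1 = m1.formula.terms[0]
        t2 = m2.formula.terms[0]
        assert ruler_length(m1, t1) == pytest.approx(ruler_length(m2, t2), abs=1e-9)


def _random_inputs(model, rng, n=50):
    out = []
    for _ in range(n):
        row = {}
        for name, spec in model.variable_specs.items():
            if spec.role == "factor":
                row[name] = str(rng.choice(list(spec.levels)))
            elif spec.role == "covariate":
                row[name] = float(rng.uniform(spec.observed_min, spec.observed_max))
        out.append(row)
    return out


class TestBuildLayout:
    @pytest.mark.parametrize("family", ["gaussian", "binomial", "poisson", "gamma"])
    def test_layout_prediction_consistency(self, family):
        # summed axis points mapped through the response rulers equal the
        # prediction module's point estimate
        spec = family_spec(family, 300, seed=91)
        bundle = generate_synthetic(spec)
        m = fit_model(bundle.table, spec.make_formula())
        layout = build_layout(m)
        rng = np.random.default_rng(7)
        for inputs in _random_inputs(m, rng, n=50):
            tp = total_points(m, layout, inputs)
            assert 0.0 - 1e-9 <= tp <= layout.total_points_range[1] + 1e-9
            resp = points_to_response(layout, tp, m)
            expected = predict_response(m, inputs).response_estimate
            assert resp == pytest.approx(expected, abs=1e-6)

    def test_cox_layout_consistency_on_linear_predictor(self):
        spec = family_spec("cox", 250, seed=93)
        bundle = generate_synthetic(spec)
        m = fit_model(bundle.table, spec.make_formula())
        layout = build_layout(m)
        rng = np.random.default_rng(11)
        for inputs in _random_inputs(m, rng, n=20):
            tp = total_points(m, layout, inputs)
            eta = layout.eta_at_zero_points + tp / layout.points_per_unit_eta
            from dynomo.prediction import _cox_eta

            _, eta_c = _cox_eta(m, inputs)
            # layout eta is the uncentered x·beta; shift by the mean term
            assert eta - float(m.covariate_means @ m.beta) == pytest.approx(
                eta_c, abs=1e-9
            )

    def test_largest_axis_reaches_100_points(self):
        m = _two_covariate_model()
        layout = build_layout(m)
        assert max(ax.max_points for ax in layout.axes) == pytest.approx(100.0)
        assert min(p for ax in layout.axes for _, p in ax.ticks) == pytest.approx(0.0)

    def test_single_term_total_range_is_100(self):
        m = _two_covariate_model(beta=(0.0, 1.0, 0.0))
        f = m.formula
        f.terms = f.terms[:1]
        m.column_labels = m.column_labels[:2]
        m.beta = m.beta[:2]
        m.sigma = m.sigma[:2, :2]
        del m.variable_specs["x2"]
        layout = build_layout(m)
        assert layout.total_points_range == (0.0, pytest.approx(100.0))

    def test_interaction_stratified_axes(self, titanic_bundle):
        from conftest import titanic_formula

        m = fit_model(titanic_bundle.table, titanic_formula(interactions=2))
        layout = build_layout(m)
        age_axes = [ax for ax in layout.axes if ax.variable == "age"]
        # one age ruler per pclass × sex combination
        assert len(age_axes) == 6
        assert {ax.stratum for ax in age_axes} == {
            f"pclass={p}, sex={s}"
            for p in ("1st", "2nd", "3rd")
            for s in ("female", "male")
        }
        rng = np.random.default_rng(3)
        for inputs in _random_inputs(m, rng, n=10):
            tp = total_points(m, layout, inputs)
            resp = points_to_response(layout, tp, m)
            assert resp == pytest.approx(
                predict_response(m, inputs).response_estimate, abs=1e-6
            )

    def test_covariate_covariate_interaction_refused(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.uniform(0, 1, 50), "b": rng.uniform(0, 1, 50)})
        df["y"] = df.a + df.b + rng.normal(0, 0.1, 50)
        f = ModelFormula(
            response="y", family="gaussian",
            terms=[TermSpec("covariate", ("a",)), TermSpec("covariate", ("b",)),
                   TermSpec("interaction", ("a", "b"))],
        )
        m = fit_model(df, f)
        with pytest.raises(LayoutUnsupportedError, match="dynamic"):
            build_layout(m)


class TestRenderSvg:
    def _layout(self):
        return build_layout(_two_covariate_model())

    def test_golden_file(self):
        svg = render_svg(self._layout(), {"title": "Toy model"})
        assert svg == GOLDEN.read_text()

    def test_well_formed_xml_with_svg_root(self):
        root = ET.fromstring(render_svg(self._layout()))
        assert root.tag.endswith("svg")
        assert root.attrib["version"] == "1.1"

    def test_axis_count_matches_layout(self):
        layout = self._layout()
        svg = render_svg(layout)
        # one label per predictor axis + Points + Total points + response
        assert svg.count('class="axis-label"') == len(layout.axes) + 3

    def test_byte_identical_rendering(self):
        assert render_svg(self._layout()) == render_svg(self._layout())

    def test_layout_json_round_trips(self):
        import json

        d = layout_to_dict(self._layout())
        json.loads(json.dumps(d))
        assert d["total_points_range"][1] >= 100.0 - 1e-9
        assert len(d["axes"]) == 2
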