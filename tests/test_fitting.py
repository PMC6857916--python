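import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from dynomo.design import build_design
from dynomo.fitting import (
    ConvergenceError,
    RankDeficiencyError,
    SeparationError,
    cox_partial_loglik,
    export_model,
    fit_cox,
    fit_glm_irls,
    fit_model,
    fit_ols,
    glm_score,
    import_model,
)
from dynomo.formula import ModelFormula, TermSpec
from dynomo.prediction import predict_response
from dynomo.synthetic import generate_synthetic

from conftest import family_spec


def _gaussian_frame(n=60, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.uniform(0, 3, n)})
    df["y"] = 2.0 + 1.5 * df.x1 - 0.7 * df.x2
    return df


def _gaussian_formula():
    return ModelFormula(
        response="y",
        family="gaussian",
        terms=[TermSpec("covariate", ("x1",)), TermSpec("covariate", ("x2",))],
    )


class TestOls:
    def test_noiseless_interpolation(self):
        df = _gaussian_frame()
        dm = build_design(df, _gaussian_formula())
        m = fit_ols(dm, df.y)
        assert np.allclose(m.beta, [2.0, 1.5, -0.7], atol=1e-10)
        assert m.dispersion < 1e-18

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        df = _gaussian_frame(seed=3)
        df["y"] = df["y"] + rng.normal(size=len(df))
        dm = build_design(df, _gaussian_formula())
        m = fit_ols(dm, df.y)
        X = dm.matrix
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ df.y.to_numpy())
        assert np.allclose(m.beta, beta_oracle, atol=1e-10)
        resid = df.y.to_numpy() - X @ beta_oracle
        s2 = resid @ resid / (len(df) - 3)
        assert np.allclose(m.sigma, s2 * np.linalg.inv(X.T @ X), atol=1e-10)
        assert m.df_residual == m.n_used - 3

    def test_rank_deficiency_names_columns(self):
        df = _gaussian_frame()
        df["x3"] = df["x1"] * 2.0
        f = ModelFormula(
            response="y",
            family="gaussian",
            terms=[TermSpec("covariate", (v,)) for v in ("x1", "x2", "x3")],
        )
        dm = build_design(df, f)
        with pytest.raises(RankDeficiencyError, match="x[13]"):
            fit_ols(dm, df.y)


class TestIrls:
    def test_gaussian_identity_equals_ols(self):
        rng = np.random.default_rng(5)
        df = _gaussian_frame(seed=5)
        df["y"] = df["y"] + rng.normal(size=len(df))
        dm = build_design(df, _gaussian_formula())
        ols = fit_ols(dm, df.y)
        irls = fit_glm_irls(dm, df.y, family="gaussian", link="identity")
        assert np.allclose(irls.beta, ols.beta, atol=1e-8)
        assert np.allclose(irls.sigma, ols.sigma, rtol=1e-6)

    def test_logistic_matches_brute_force_mle(self):
        # 20-row problem: independent maximization of the written-out
        # Bernoulli log-likelihood
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"x1": rng.normal(size=20)})
        df["y"] = (rng.uniform(size=20) < 1 / (1 + np.exp(-0.5 * df.x1))).astype(float)
        f = ModelFormula(response="y", family="binomial",
                         terms=[TermSpec("covariate", ("x1",))])
        dm = build_design(df, f)
        m = fit_glm_irls(dm, df.y)

        X, y = dm.matrix, df.y.to_numpy()

        def negll(beta):
            eta = X @ beta
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        res = minimize(negll, np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-12})
        assert np.abs(m.beta - res.x).max() < 1e-5

    @pytest.mark.parametrize("family", ["binomial", "poisson", "gamma"])
    def test_matches_statsmodels(self, family):
        import statsmodels.api as sm

        spec = family_spec(family, 400, seed=23)
        b = generate_synthetic(spec)
        f = spec.make_formula()
        dm = build_design(b.table, f)
        y = b.table.y.to_numpy()
        m = fit_glm_irls(dm, y)
        fam = {
            "binomial": sm.families.Binomial(),
            "poisson": sm.families.Poisson(),
            "gamma": sm.families.Gamma(),
        }[family]
        ref = sm.GLM(y, dm.matrix, family=fam).fit()
        assert np.abs(m.beta - ref.params).max() < 1e-6
        assert np.abs(np.sqrt(np.diag(m.sigma)) - ref.bse).max() < 1e-4

    @pytest.mark.parametrize("family", ["binomial", "poisson", "gaussian", "gamma"])
    def test_score_vanishes_at_optimum(self, family):
        spec = family_spec(family, 500, seed=31)
        b = generate_synthetic(spec)
        dm = build_design(b.table, spec.make_formula())
        m = fit_glm_irls(dm, b.table.y)
        score = glm_score(dm, b.table.y, m.beta, family, m.link)
        assert np.abs(score).max() < 1e-6 * m.n_used

    def test_separation_raises(self):
        df = pd.DataFrame({"x1": np.r_[np.zeros(10), np.ones(10)],
                           "y": np.r_[np.zeros(10), np.ones(10)]})
        f = ModelFormula(response="y", family="binomial",
                         terms=[TermSpec("covariate", ("x1",))])
        dm = build_design(df, f)
        with pytest.raises((SeparationError, ConvergenceError)) as exc:
            fit_glm_irls(dm, df.y)
        assert getattr(exc.value, "trace", None)

    def test_response_support_validation(self):
        df = pd.DataFrame({"x1": np.arange(10.0), "y": np.arange(10.0) - 5})
        f = ModelFormula(response="y", family="gamma",
                         terms=[TermSpec("covariate", ("x1",))])
        dm = build_design(df, f)
        with pytest.raises(ValueError, match="positive"):
            fit_glm_irls(dm, df.y)


def _cox_frame(n=8, seed=2):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "x": np.r_[np.zeros(n // 2), np.ones(n // 2)],
            "time": rng.exponential(5, n).round(1) + 0.1,
            "status": rng.integers(0, 2, n) | 1,  # mostly events
        }
    )


def _cox_formula():
    return ModelFormula(response=None, family="cox", time="time",
                        status="status", terms=[TermSpec("covariate", ("x",))])


class TestCox:
    def test_matches_grid_search_oracle(self):
        # 8 subjects, one binary covariate: 1-D grid over the written-out
        # partial likelihood
        df = _cox_frame()
        dm = build_design(df, _cox_formula())
        m = fit_cox(dm, df.time, df.status, ties="efron")
        Xc = dm.matrix - dm.matrix.mean(axis=0)
        grid = np.linspace(m.beta[0] - 1, m.beta[0] + 1, 20001)
        lls = [cox_partial_loglik(Xc, df.time, df.status, [b], "efron") for b in grid]
        assert abs(grid[int(np.argmax(lls))] - m.beta[0]) < 1e-4

    def test_subject_order_invariance(self):
        df = _cox_frame(n=40, seed=9)
        dm = build_design(df, _cox_formula())
        m1 = fit_cox(dm, df.time, df.status)
        perm = np.random.default_rng(0).permutation(len(df))
        dfp = df.iloc[perm].reset_index(drop=True)
        dmp = build_design(dfp, _cox_formula())
        m2 = fit_cox(dmp, dfp.time, dfp.status)
        assert np.allclose(m1.beta, m2.beta, atol=1e-10)

    def test_time_transform_invariance(self):
        # any strictly increasing transform preserving event order leaves
        # the partial-likelihood estimate unchanged
        df = _cox_frame(n=40, seed=13)
        dm = build_design(df, _cox_formula())
        m1 = fit_cox(dm, df.time, df.status)
        m2 = fit_cox(dm, df.time ** 1.5, df.status)
        assert np.allclose(m1.beta, m2.beta, atol=1e-8)

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        spec = family_spec("cox", 300, seed=17)
        b = generate_synthetic(spec)
        f = spec.make_formula()
        m = fit_model(b.table, f)
        df = b.table.copy()
        df["gb"] = (df.g == "b").astype(float)
        cph = CoxPHFitter().fit(df[["time", "status", "x", "gb"]], "time", "status")
        assert np.abs(m.beta - cph.params_.to_numpy()).max() < 1e-5
        assert np.abs(np.sqrt(np.diag(m.sigma)) - cph.standard_errors_.to_numpy()).max() < 1e-5

    def test_no_events_errors(self):
        df = _cox_frame()
        df["status"] = 0
        dm = build_design(df, _cox_formula())
        with pytest.raises(ValueError, match="no events"):
            fit_cox(dm, df.time, df.status)

    def test_intercept_design_rejected(self):
        df = _cox_frame()
        f = ModelFormula(response="time", family="gaussian",
                         terms=[TermSpec("covariate", ("x",))])
        dm = build_design(df, f)
        with pytest.raises(ValueError, match="intercept"):
            fit_cox(dm, df.time, df.status)


class TestBreslowBaseline:
    def test_hand_nelson_aalen(self, three_subject_cox):
        # d/S0 increments at beta=0: 1/3 then 1/3 + 1/2
        assert np.allclose(three_subject_cox.event_times, [1.0, 2.0])
        assert np.allclose(three_subject_cox.baseline_cumhaz, [1 / 3, 1 / 3 + 1 / 2])
        assert np.array_equal(three_subject_cox.at_risk, [3, 2])

    def test_monotone(self):
        spec = family_spec("cox", 200, seed=29)
        b = generate_synthetic(spec)
        m = fit_model(b.table, spec.make_formula())
        assert np.all(np.diff(m.baseline_cumhaz) >= 0)
        assert np.all(np.diff(m.at_risk) <= 0)

    def test_replicating_every_subject_preserves_baseline(self):
        df = _cox_frame(n=20, seed=4)
        dm = build_design(df, _cox_formula())
        m1 = fit_cox(dm, df.time, df.status)
        df2 = pd.concat([df, df], ignore_index=True)
        dm2 = build_design(df2, _cox_formula())
        # evaluate the baseline at the original beta for a clean comparison
        from dynomo.fitting import _breslow_baseline_arrays

        Xc1 = dm.matrix - dm.matrix.mean(axis=0)
        Xc2 = dm2.matrix - dm2.matrix.mean(axis=0)
        b1 = _breslow_baseline_arrays(Xc1, df.time.to_numpy(), df.status.to_numpy(), m1.beta)
        b2 = _breslow_baseline_arrays(Xc2, df2.time.to_numpy(), df2.status.to_numpy(), m1.beta)
        assert np.allclose(b1["cumhaz"], b2["cumhaz"], atol=1e-12)


class TestImportExport:
    def test_round_trip_reproduces_predictions_bit_identically(self, binomial_bundle):
        spec = binomial_bundle.generating
        m = fit_model(binomial_bundle.table, spec.make_formula())
        doc = export_model(m)
        m2 = import_model(doc)
        x = {"x": 1.2, "g": "b"}
        r1 = predict_response(m, x)
        r2 = predict_response(m2, x)
        assert r1.response_estimate == r2.response_estimate
        assert r1.response_lower == r2.response_lower
        assert r1.response_upper == r2.response_upper

    def test_cox_round_trip(self):
        spec = family_spec("cox", 150, seed=77)
        b = generate_synthetic(spec)
        m = fit_model(b.table, spec.make_formula())
        m2 = import_model(export_model(m))
        from dynomo.prediction import survival_curve

        x = {"x": 1.0, "g": "a"}
        assert np.array_equal(survival_curve(m, x).survival,
                              survival_curve(m2, x).survival)

    def test_asymmetric_sigma_rejected(self, binomial_bundle):
        m = fit_model(binomial_bundle.table, binomial_bundle.generating.make_formula())
        doc = export_model(m)
        doc["sigma"][0][1] = doc["sigma"][0][1] + 1.0
        with pytest.raises(ValueError, match="symmetric"):
            import_model(doc)

    def test_dimension_mismatch_rejected(self, binomial_bundle):
        m = fit_model(binomial_bundle.table, binomial_bundle.generating.make_formula())
        doc = export_model(m)
        doc["beta"] = doc["beta"][:-1]
        with pytest.raises(ValueError, match="dimension"):
            import_model(doc)

    def test_hand_written_logistic_json(self):
        # two-coefficient logistic model written by hand: predictions are
        # the inverse logit of beta0 + beta1 x
        doc = {
            "format": "dynomo-model", "version": 1, "family": "binomial",
            "link": "logit", "columns": ["(Intercept)", "x"],
            "beta": [-1.0, 2.0], "sigma": [[0.0, 0.0], [0.0, 0.0]],
            "dispersion": 1.0, "df_residual": 98, "n_used": 100, "loglik": 0.0,
            "formula": {
                "response": "y", "family": "binomial", "link": "logit",
                "time": None, "status": None,
                "terms": [{"kind": "covariate", "variables": ["x"],
                           "spline_knots": [], "spline_df": None}],
            },
            "variable_specs": {
                "x": {"name": "x", "role": "covariate", "levels": [],
                      "observed_min": 0.0, "observed_max": 1.0,
                      "mean": 0.5, "mode": None}
            },
        }
        m = import_model(doc)
        r = predict_response(m, {"x": 0.5})
        assert r.response_estimate == pytest.approx(1 / (1 + np.exp(0.0)), abs=1e-12)
        r2 = predict_response(m, {"x": 1.0})
        assert r2.response_estimate == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-12)
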