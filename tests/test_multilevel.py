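"""Poisson GLMM: quadrature accuracy, oracle limits, parameter recovery."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import integrate, stats

from scdkit.multilevel import (RegressionSpec, collapse_cells, fit_glmm_poisson,
                               fit_poisson_fe, fit_poisson_re,
                               ghq_marginal_loglik, marginal_loglik,
                               simulate_two_group_glmm)
from scdkit.scd_scoring import calibrate_from_survey, flag_scd
from scdkit.survey_io import SurveyTable


@pytest.fixture(scope="module")
def toy_cell():
    rng = np.random.default_rng(0)
    eta = rng.normal(-2.0, 0.5, 5)
    y = (rng.random(5) < 0.3).astype(float)
    return eta, y


class TestQuadrature:
    def test_zero_variance_equals_conditional_loglik(self, toy_cell):
        eta, y = toy_cell
        cond = float((y * eta - np.exp(eta)).sum())
        assert ghq_marginal_loglik(eta, y, 0.0) == pytest.approx(cond, abs=1e-12)

    def test_matches_dense_grid_oracle(self, toy_cell):
        eta, y = toy_cell
        var = 0.6

        def integrand(b):
            return np.exp((y * (eta + b) - np.exp(eta + b)).sum()) * \
                stats.norm.pdf(b, 0, np.sqrt(var))

        grid, err = integrate.quad(integrand, -10, 10, limit=400)
        assert err < 1e-10
        ll = ghq_marginal_loglik(eta, y, var, n_quad=15)
        assert ll == pytest.approx(np.log(grid), abs=1e-6)

    def test_monotone_convergence_in_nodes(self, toy_cell):
        eta, y = toy_cell
        lls = [ghq_marginal_loglik(eta, y, 0.5, nq) for nq in (3, 7, 15, 31)]
        diffs = np.abs(np.diff(lls))
        assert (np.diff(diffs) < 0).all()
        assert diffs[-1] < 1e-8

    def test_invalid_nodes_rejected(self, toy_cell):
        eta, y = toy_cell
        with pytest.raises(ValueError):
            ghq_marginal_loglik(eta, y, 0.5, 0)


class TestDegenerateLimits:
    def test_variance_zero_matches_glm_oracle(self):
        y, X, g = simulate_two_group_glmm(np.random.default_rng(1), 10, 500)
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        data = collapse_cells(y, X, g, np.ones((len(y), 1)))
        ours = marginal_loglik(np.asarray(glm.params), np.array([0.0]), data)
        assert ours == pytest.approx(glm.llf, abs=1e-8)
        # and the near-zero-variance MLE of beta matches the GLM solution
        fit = fit_glmm_poisson(y, X, g, np.ones((len(y), 1)),
                               start=np.array([*glm.params, np.log(1e-6)]))
        assert np.abs(fit.params.to_numpy() - glm.params).max() < 1e-4

    def test_single_country_fe_equals_plain_poisson(self):
        rng = np.random.default_rng(2)
        n = 2000
        male = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < np.exp(-2.2 + 0.3 * male)).astype(float)
        frame = make_frame(male, y, "AA")
        spec = RegressionSpec(exposures=("sex",),
                              references={"sex": "female"}, age_range=(36, 59))
        fe = fit_poisson_fe(SurveyTable(frame), spec)
        X = np.column_stack([np.ones(n), male])
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert fe.params["sex[male]"] == pytest.approx(glm.params[1], abs=1e-8)


class TestRandomEffects:
    def test_loglik_trace_monotone_nonincreasing(self):
        y, X, g = simulate_two_group_glmm(np.random.default_rng(3), 15, 800)
        Z = np.column_stack([np.ones(len(y)), X[:, 1]])
        fit = fit_glmm_poisson(y, X, g, Z, track_trace=True,
                               param_names=["intercept", "male"])
        trace = np.array(fit.trace)
        assert (np.diff(trace) <= 1e-8).all()

    def test_null_slope_variance_matches_intercept_model(self):
        # data with no slope heterogeneity: slope-variance estimate pins near
        # zero and beta agrees with the random-intercept-only fit
        y, X, g = simulate_two_group_glmm(
            np.random.default_rng(4), 20, 1500, sd_slope=0.0)
        Z2 = np.column_stack([np.ones(len(y)), X[:, 1]])
        both = fit_glmm_poisson(y, X, g, Z2, param_names=["intercept", "male"])
        icpt = fit_glmm_poisson(y, X, g, np.ones((len(y), 1)),
                                param_names=["intercept", "male"])
        assert both.re_sd["sd_1"] < 0.05
        assert both.params["male"] == pytest.approx(icpt.params["male"], abs=5e-3)

    def test_recovers_true_prr_two(self):
        # strong wealth-style binary exposure with true PRR 2 at large n
        rng = np.random.default_rng(5)
        y, X, g = simulate_two_group_glmm(
            rng, 40, 5000, beta0=np.log(0.05), beta1=np.log(2.0),
            sd_intercept=0.3, sd_slope=0.1)
        Z = np.column_stack([np.ones(len(y)), X[:, 1]])
        fit = fit_glmm_poisson(y, X, g, Z, param_names=["intercept", "exposed"])
        assert fit.converged
        assert 1.9 <= float(fit.prr["exposed"]) <= 2.1


class TestFixedEffects:
    def test_multi_exposure_recovery(self, default_survey):
        # the generator's latent effects imply male PRR > 1 and a monotone
        # wealth gradient; check signs and ordering rather than magnitudes
        cuts, _ = calibrate_from_survey(default_survey)
        frame = default_survey.children.copy()
        frame["scd"] = flag_scd(default_survey, cuts)
        table = SurveyTable(frame, default_survey.meta)
        fit = fit_poisson_fe(table, RegressionSpec())
        assert fit.converged
        assert fit.prr["sex[male]"] > 1.0
        q = [fit.prr[f"wealth_quintile[{k}]"] for k in (1, 2, 3, 4)]
        assert q[0] > 1.0 and q[0] == max(q)
        assert fit.prr["ece_enrolled[no]"] > 1.0
        assert fit.prr["maternal_education[none_preprimary]"] > 1.0

    def test_degenerate_country_dropped_and_flagged(self):
        rng = np.random.default_rng(6)
        n = 500
        male = rng.integers(0, 2, 2 * n).astype(float)
        y = np.concatenate([
            np.zeros(n),                                   # country with no SCD
            (rng.random(n) < 0.1).astype(float),
        ])
        frame = make_frame(male, y, None,
                           codes=np.repeat(["AA", "BB"], n))
        spec = RegressionSpec(exposures=("sex",), references={"sex": "female"})
        fit = fit_poisson_fe(SurveyTable(frame), spec)
        assert fit.dropped_groups == ["AA"]
        assert fit.n == n


def make_frame(male, y, code, codes=None):
    import pandas as pd
    from scdkit.survey_io import ITEMS
    n = len(y)
    frame = pd.DataFrame({
        "country_code": codes if codes is not None else code,
        "cluster_id": "K1", "household_id": [f"H{i}" for i in range(n)],
        "child_id": [f"B{i}" for i in range(n)],
        "age_months": 48, "sex": np.where(male > 0, "male", "female"),
        "maternal_education": "primary", "ece_enrolled": "no",
        "wealth_quintile": pd.array([3] * n, dtype="Float64"),
        "child_weight": 1.0, "scd": y,
    })
    for it in ITEMS:
        frame[it] = 1.0
    return frame
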