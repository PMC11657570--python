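"""Marginal-likelihood machinery: quadrature, modes, fitting, SEs."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, poisson

from ziclust.families import zi_obs_loglik
from ziclust.model import (
    ModelSpec,
    TwoLevelCountModel,
    cluster_marginal_loglik,
    fit_model,
    significance_tier,
    total_loglik,
)


def dense_grid_loglik_1d(y, eta0, sigma_u, n_grid=20_001, span=8.0):
    """Brute-force marginal likelihood: trapezoid over a +-span*sigma grid."""
    u = np.linspace(-span * sigma_u, span * sigma_u, n_grid)
    ll = np.array(
        [
            poisson.logpmf(y, np.exp(eta0 + uk)).sum() + norm.logpdf(uk, 0, sigma_u)
            for uk in u
        ]
    )
    mx = ll.max()
    return float(np.log(np.trapezoid(np.exp(ll - mx), u)) + mx)


class TestClusterMarginal:
    def test_degenerate_sigma_equals_conditional(self):
        y = np.array([0, 2, 5])
        X = np.ones((3, 1))
        got = cluster_marginal_loglik(y, X, [0.3], 0.0, family="poisson")
        expect = float(zi_obs_loglik(y, 0.0, 0.3, "poisson").sum())
        assert got == pytest.approx(expect, abs=1e-12)

    def test_dense_grid_oracle_1d(self):
        y = np.array([0, 2, 5])
        X = np.ones((3, 1))
        oracle = dense_grid_loglik_1d(y, 0.3, 0.5)
        got = cluster_marginal_loglik(y, X, [0.3], 0.5, family="poisson", K=15)
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_dense_grid_oracle_2d(self):
        # zero-inflated: integrate both random intercepts
        y = np.array([0, 0, 3])
        X = np.ones((3, 1))
        alpha0, beta0, sw, su = 0.5, 0.3, 0.4, 0.5
        gw = np.linspace(-8 * sw, 8 * sw, 1201)
        gu = np.linspace(-8 * su, 8 * su, 1201)
        WW, UU = np.meshgrid(gw, gu, indexing="ij")
        F = np.zeros_like(WW)
        for yy in y:
            phi = 1.0 / (1.0 + np.exp(-(alpha0 + WW)))
            lam = np.exp(beta0 + UU)
            if yy == 0:
                F += np.log(phi + (1 - phi) * np.exp(-lam))
            else:
                F += np.log(1 - phi) + yy * (beta0 + UU) - lam - math.lgamma(yy + 1)
        F += norm.logpdf(WW, 0, sw) + norm.logpdf(UU, 0, su)
        mx = F.max()
        inner = np.trapezoid(np.exp(F - mx), gu, axis=1)
        oracle = float(np.log(np.trapezoid(inner, gw)) + mx)
        got = cluster_marginal_loglik(
            y, X, [beta0], su, exog_zero=X, alpha=[alpha0], sigma_w=sw,
            zero_inflated=True, family="poisson", K=15,
        )
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_quadrature_self_convergence(self):
        y = np.array([1, 0, 2, 4, 0])
        X = np.column_stack([np.ones(5), [0, 1, 0, 1, 1]])
        k15 = cluster_marginal_loglik(y, X, [0.2, 0.5], 0.4, family="poisson", K=15)
        k30 = cluster_marginal_loglik(y, X, [0.2, 0.5], 0.4, family="poisson", K=30)
        assert abs(k15 - k30) < 1e-8


class TestTotalLoglik:
    def test_saturated_zero_model(self):
        df = pd.DataFrame({"city_id": ["a"] * 5 + ["b"] * 5, "y": [0] * 10,
                           "sex": ["Female"] * 10})
        spec = ModelSpec("poisson", True, ("sex",), ("sex",))
        # phi -> 1 via a huge zero-part intercept: loglik -> 0 from below
        params = np.array([0.0, 0.0, 25.0, 0.0, np.log(1e-6), np.log(1e-6)])
        ll = total_loglik(df, spec, params, K=7)
        assert -1e-6 < ll <= 0.0

    def test_matches_cluster_sum_oracle(self, tiny_cluster_frame):
        spec = ModelSpec("poisson", False, ("sex",), None)
        params = np.array([0.1, 0.4, np.log(0.5)])
        ll = total_loglik(tiny_cluster_frame, spec, params, K=25)
        oracle = 0.0
        for _, g in tiny_cluster_frame.groupby("city_id"):
            eta0 = 0.1 + 0.4 * (g["sex"] == "Male").to_numpy()
            u = np.linspace(-4, 4, 20_001)
            llg = np.array(
                [
                    poisson.logpmf(g["y"].to_numpy(), np.exp(eta0 + uk)).sum()
                    + norm.logpdf(uk, 0, 0.5)
                    for uk in u
                ]
            )
            mx = llg.max()
            oracle += float(np.log(np.trapezoid(np.exp(llg - mx), u)) + mx)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_sigma_to_zero_continuity(self, tiny_cluster_frame):
        spec = ModelSpec("poisson", False, ("sex",), None)
        fixed = np.array([0.1, 0.4])
        ll_tiny = total_loglik(
            tiny_cluster_frame, spec, np.append(fixed, np.log(1e-6)), K=15
        )
        model = TwoLevelCountModel.from_dataframe(tiny_cluster_frame, spec)
        ll_fixed = model.conditional_loglik(fixed, np.zeros(0), None)
        assert ll_tiny == pytest.approx(ll_fixed, abs=1e-6)


class TestScoreGradient:
    @pytest.mark.parametrize(
        "family,disp,zi",
        [("poisson", None, True), ("negbin", 1.5, False), ("cmp", 0.5, True)],
    )
    def test_analytic_score_matches_finite_differences(self, family, disp, zi):
        rng = np.random.default_rng(2)
        m, per = 6, 25
        ci = np.repeat(np.arange(m), per)
        n = m * per
        x = rng.random(n) < 0.4
        X = np.column_stack([np.ones(n), x.astype(float)])
        y = rng.poisson(1.0, n)
        y[rng.random(n) < 0.5] = 0
        model = TwoLevelCountModel(
            y, X, ci, exog_zero=X if zi else None, family=family, zero_inflated=zi
        )
        th = [0.2, 0.4]
        if zi:
            th += [0.5, -0.3]
        if model.family.has_dispersion:
            th += [math.log(disp)]
        th += [math.log(0.3)]
        if zi:
            th += [math.log(0.25)]
        th = np.array(th)
        g = model.score(th, K=11)
        eps = 1e-6
        for j in range(th.size):
            d = np.zeros_like(th)
            d[j] = eps
            model._mode_cache = None
            lp = model.loglike(th + d, K=11)
            model._mode_cache = None
            lm = model.loglike(th - d, K=11)
            fd = (lp - lm) / (2 * eps)
            assert g[j] == pytest.approx(fd, rel=2e-4, abs=2e-4)


class TestParameterCounts:
    SPECS = [
        (ModelSpec("poisson", False), 25),
        (ModelSpec("negbin", False), 26),
        (ModelSpec("cmp", False), 26),
        (ModelSpec("poisson", True), 50),
        (ModelSpec("negbin", True), 51),
        (ModelSpec("cmp", True), 51),
    ]

    @pytest.mark.parametrize("spec,expected", SPECS)
    def test_full_coding_parameter_count(self, spec, expected):
        # 24 fixed effects per part + dispersion (NB/CMP) + active RE SDs
        df = pd.DataFrame(
            {
                "city_id": ["a", "b"],
                "y": [0, 3],
                "age_group": ["<=20", ">30"],
                "sex": ["Female", "Male"],
                "bmi_class": ["Normal", "Obese"],
                "marital": ["Married", "Single"],
                "education": ["Diploma", "AD/BSc"],
                "occupation": ["Housewife", "Freelance"],
                "residence": ["Urban", "Rural"],
                "disease_hist": ["No", "Yes"],
                "fam_mental": ["No", "Yes"],
                "fam_chronic": ["Yes", "No"],
                "general_study": ["No", "Yes"],
                "hookah": ["No", "Yes"],
            }
        )
        model = TwoLevelCountModel.from_dataframe(df, spec)
        assert model.k_params == expected


class TestFitting:
    def test_poisson_recovery_within_3se(self):
        rng = np.random.default_rng(4)
        m = 29
        sizes = rng.integers(40, 100, m)
        ci = np.repeat(np.arange(m), sizes)
        n = ci.size
        x = (rng.random(n) < 0.4).astype(float)
        X = np.column_stack([np.ones(n), x])
        beta = np.array([0.4, 0.7])
        u = rng.normal(0, 0.3, m)
        y = rng.poisson(np.exp(X @ beta + u[ci]))
        model = TwoLevelCountModel(y, X, ci, family="poisson")
        res = model.fit(K=9)
        assert res.converged
        truth = np.array([0.4, 0.7, math.log(0.3)])
        assert np.all(np.abs(res.params - truth) < 3 * res.bse)

    def test_degenerate_mixture_recovery(self):
        # ZI model fitted to data with no structural zeros at all
        rng = np.random.default_rng(5)
        m = 20
        ci = np.repeat(np.arange(m), 60)
        n = ci.size
        x = (rng.random(n) < 0.5).astype(float)
        X = np.column_stack([np.ones(n), x])
        beta = np.array([0.8, 0.5])
        y = rng.poisson(np.exp(X @ beta + rng.normal(0, 0.2, m)[ci]))
        model = TwoLevelCountModel(
            y, X, ci, exog_zero=X, family="poisson", zero_inflated=True
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(K=7)
        phi_hat = 1.0 / (1.0 + np.exp(-res.alpha[0]))
        assert phi_hat < 0.05  # mixing probability near the boundary
        se = res.bse
        assert abs(res.beta[0] - 0.8) < 3 * max(se[0], 0.05)
        assert abs(res.beta[1] - 0.5) < 3 * max(se[1], 0.05)

    def test_intercept_se_closed_form(self):
        # iid Poisson with the random effect pinned at ~0: the observed
        # information for the intercept is n * mu_hat, so SE = 1/sqrt(n mu_hat)
        rng = np.random.default_rng(6)
        n, m = 2900, 29
        y = rng.poisson(3.0, n)
        ci = np.repeat(np.arange(m), n // m)
        model = TwoLevelCountModel(y, np.ones((n, 1)), ci, family="poisson")
        mu_hat = y.mean()
        th = np.array([math.log(mu_hat), math.log(1e-6)])
        h = 1e-6
        d = np.array([h, 0.0])
        info00 = -(model.score(th + d, K=7)[0] - model.score(th - d, K=7)[0]) / (2 * h)
        assert info00 == pytest.approx(n * mu_hat, rel=1e-5)
        closed = 1.0 / math.sqrt(n * mu_hat)
        assert 1.0 / math.sqrt(info00) == pytest.approx(closed, abs=1e-4)

    def test_vcov_symmetric(self, sex_only_poisson_data):
        _, df = sex_only_poisson_data
        spec = ModelSpec("poisson", True, ("sex",), ("sex",))
        res = fit_model(df, spec, K=5)
        V = res.cov_params()
        assert np.allclose(V, V.T, rtol=1e-6, atol=1e-12)

    def test_loglik_k15_vs_k30_at_optimum(self, sex_only_poisson_data):
        _, df = sex_only_poisson_data
        spec = ModelSpec("poisson", True, ("sex",), ("sex",))
        model = TwoLevelCountModel.from_dataframe(df, spec)
        res = model.fit(K=15)
        model._mode_cache = None
        a = model.loglike(res.params, K=15)
        model._mode_cache = None
        b = model.loglike(res.params, K=30)
        assert abs(a - b) < 1e-6

    def test_zi_nests_base_family(self, sex_only_poisson_data):
        _, df = sex_only_poisson_data
        base = fit_model(df, ModelSpec("poisson", False, ("sex",), None), K=7)
        zi = fit_model(df, ModelSpec("poisson", True, ("sex",), ("sex",)), K=7)
        assert zi.llf >= base.llf - 1e-4

    def test_separation_yields_boundary_with_warning(self):
        # one covariate level entirely non-smoking: zero-part separation
        rng = np.random.default_rng(8)
        n, m = 400, 8
        ci = np.repeat(np.arange(m), n // m)
        x = (np.arange(n) % 2).astype(float)
        X = np.column_stack([np.ones(n), x])
        y = np.where(x == 1, 0, rng.poisson(2.0, n))
        model = TwoLevelCountModel(
            y, X, ci, exog_zero=X, family="poisson", zero_inflated=True
        )
        with pytest.warns(UserWarning):
            res = model.fit(K=5)
            res.cov_params()
        assert res.alpha[1] > 3.0  # boundary-sized estimate

    def test_too_few_clusters_warns(self):
        y = np.array([0, 1, 2, 0])
        X = np.ones((4, 1))
        model = TwoLevelCountModel(y, X, np.zeros(4, dtype=int), family="poisson")
        with pytest.warns(UserWarning, match="fewer than 2 clusters"):
            model.fit(K=3, maxiter=20)


class TestResultsSurface:
    def test_summary_and_accessors(self, sex_only_poisson_data):
        _, df = sex_only_poisson_data
        spec = ModelSpec("poisson", True, ("sex",), ("sex",))
        res = fit_model(df, spec, K=5)
        text = res.summary()
        assert "TL-ZIP" in text and "log-likelihood" in text
        assert "count:sex[Male]" in text and "zero:sex[Male]" in text
        assert res.random_effects.shape == (29, 3)
        fitted = res.fitted()
        assert fitted.shape == (len(df),)
        assert np.all(fitted >= 0)
        # marginal fitted means differ once random effects are nonzero
        assert not np.allclose(fitted, res.fitted(conditional=False))

    def test_significance_tiers(self):
        assert significance_tier(0.0005) == "***"
        assert significance_tier(0.005) == "**"
        assert significance_tier(0.02) == "*"
        assert significance_tier(0.2) == ""

    def test_input_validation(self):
        with pytest.raises(ValueError):
            TwoLevelCountModel(np.array([1, -2]), np.ones((2, 1)), [0, 1])
        with pytest.raises(ValueError):
            TwoLevelCountModel(
                np.array([1, 2]), np.ones((2, 1)), [0, 1], zero_inflated=True
            )
        with pytest.raises(ValueError):
            model = TwoLevelCountModel(np.array([1, 2]), np.ones((2, 1)), [0, 1])
            model.loglike(np.zeros(5))
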