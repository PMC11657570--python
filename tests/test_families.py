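"""Observation-level likelihood terms for the six model families."""

import math

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import nbinom, poisson

from ziclust.cmp import CMPParams, cmp_logpmf, cmp_moments
from ziclust.families import (
    count_logpmf,
    fitted_mean,
    get_family,
    linear_predictors,
    nb_mu_from_rp,
    zi_obs_loglik,
)


class TestLinearPredictors:
    def test_zero_vectors(self):
        xi, eta = linear_predictors([0.0], [0.0], [0.0], [0.0])
        assert (xi, eta) == (0.0, 0.0)
        # phi = logistic(0) = 0.5, rate = exp(0) = 1
        assert 1.0 / (1.0 + math.exp(-xi)) == 0.5

    def test_published_male_odds(self):
        # intercept-only zero part with the male coefficient: the implied
        # odds of a structural zero are exp(-2.26432) = 0.1039
        xi, _ = linear_predictors([1.0], [-2.26432], [1.0], [0.0])
        phi = 1.0 / (1.0 + math.exp(-xi))
        assert round(phi / (1.0 - phi), 4) == 0.1039

    def test_dot_product_oracle(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=24)
        beta = rng.normal(size=24)
        expected = sum(float(x) * float(c) for x, c in zip(b, beta))
        _, eta = linear_predictors(np.zeros(3), np.zeros(3), b, beta, u=0.25)
        assert eta == pytest.approx(expected + 0.25, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            linear_predictors([1.0, 0.0], [1.0], [1.0], [1.0])


class TestCountLogpmf:
    def test_poisson_at_zero(self):
        assert count_logpmf(0, 0.0, "poisson") == pytest.approx(-1.0, abs=1e-14)

    def test_poisson_matches_scipy(self):
        y = np.arange(15)
        out = count_logpmf(y, math.log(2.5), "poisson")
        assert np.allclose(out, poisson.logpmf(y, 2.5), atol=1e-12)

    def test_nb_direct_formula(self):
        # NB2 with mean mu and dispersion r against the Gamma-function form
        y, mu, r = 2, 1.5, 2.0
        expected = (
            gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
            + r * math.log(r / (r + mu)) + y * math.log(mu / (r + mu))
        )
        assert count_logpmf(y, math.log(mu), "negbin", r) == pytest.approx(
            expected, abs=1e-12
        )
        # and against scipy's (n, p) parameterization, p = r / (r + mu)
        assert count_logpmf(y, math.log(mu), "negbin", r) == pytest.approx(
            float(nbinom.logpmf(y, r, r / (r + mu))), abs=1e-12
        )

    def test_nb_poisson_limit(self):
        y = np.arange(21)
        eta = math.log(3.0)
        nb = count_logpmf(y, eta, "negbin", 1e8)
        po = count_logpmf(y, eta, "poisson")
        assert np.max(np.abs(nb - po)) < 1e-5

    def test_cmp_delegates(self):
        val = count_logpmf(3, math.log(2.0), "cmp", 0.5)
        assert val == pytest.approx(cmp_logpmf(3, CMPParams(2.0, 0.5)), abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            count_logpmf(-1, 0.0, "poisson")
        with pytest.raises(ValueError):
            count_logpmf(2, 0.0, "negbin")  # missing dispersion
        with pytest.raises(ValueError):
            count_logpmf(2, 0.0, "weibull")


class TestZeroInflation:
    @pytest.mark.parametrize(
        "family,disp", [("poisson", None), ("negbin", 1.75), ("cmp", 0.38)]
    )
    def test_phi_zero_reduces_to_count(self, family, disp):
        y = np.arange(8)
        zi = zi_obs_loglik(y, 0.0, 0.4, family, disp)
        base = count_logpmf(y, 0.4, family, disp)
        assert np.max(np.abs(zi - base)) < 1e-12

    def test_phi_one_at_zero(self):
        assert zi_obs_loglik(0, 1.0, 2.0, "poisson") == pytest.approx(0.0, abs=1e-14)

    def test_hand_computation(self):
        # phi = 0.9, Poisson rate 4: P(0) = 0.9 + 0.1 e^-4
        val = zi_obs_loglik(0, 0.9, math.log(4.0), "poisson")
        assert val == pytest.approx(math.log(0.9 + 0.1 * math.exp(-4.0)), abs=1e-12)

    def test_tiny_mixture_is_stable(self):
        # both phi and f(0) minuscule: plain arithmetic would underflow
        val = zi_obs_loglik(0, 1e-300, 25.0, "poisson")
        assert np.isfinite(val)

    def test_phi_validation(self):
        with pytest.raises(ValueError):
            zi_obs_loglik(0, 1.2, 0.0, "poisson")

    @pytest.mark.parametrize(
        "family,disp,phi",
        [
            ("poisson", None, 0.0),
            ("poisson", None, 0.3),
            ("negbin", 1.75, 0.3),
            ("negbin", 0.071, 0.5),
            ("cmp", 0.38, 0.3),
            ("cmp", 1.75, 0.0),
        ],
    )
    def test_mixture_is_distribution(self, family, disp, phi):
        y = np.arange(400)
        ll = zi_obs_loglik(y, phi, math.log(2.0), family, disp)
        assert np.exp(ll).sum() == pytest.approx(1.0, abs=1e-8)


class TestFittedMean:
    def test_poisson_cases(self):
        assert fitted_mean(0.0, math.log(3.0), "poisson") == pytest.approx(3.0)
        assert fitted_mean(0.5, math.log(3.0), "poisson") == pytest.approx(1.5)

    def test_cmp_case(self):
        mean, _ = cmp_moments(CMPParams(2.0, 0.5))
        assert fitted_mean(0.3, math.log(2.0), "cmp", 0.5) == pytest.approx(
            0.7 * mean, rel=1e-9
        )


class TestScoresAndCurvature:
    """Analytic eta/dispersion derivatives against central differences."""

    @pytest.mark.parametrize(
        "family,disp", [("poisson", None), ("negbin", 1.6), ("cmp", 0.45)]
    )
    def test_score_and_curvature_in_eta(self, family, disp):
        fam = get_family(family)
        y = np.array([0.0, 1.0, 4.0, 9.0])
        eta = np.array([-0.5, 0.2, 0.8, 1.3])
        dargs = (disp,) if fam.has_dispersion else ()
        h = 1e-6
        fd_s = (fam.logpmf(y, eta + h, *dargs) - fam.logpmf(y, eta - h, *dargs)) / (2 * h)
        assert np.allclose(fam.score_eta(y, eta, *dargs), fd_s, atol=1e-5)
        fd_h = (
            fam.score_eta(y, eta + h, *dargs) - fam.score_eta(y, eta - h, *dargs)
        ) / (2 * h)
        assert np.allclose(fam.d2_eta(y, eta, *dargs), fd_h, atol=1e-4)
        # zero-count specializations agree with the general forms at y = 0
        assert np.allclose(
            fam.score_eta0(eta, *dargs), fam.score_eta(np.zeros(4), eta, *dargs)
        )

    @pytest.mark.parametrize("family,disp", [("negbin", 1.6), ("cmp", 0.45)])
    def test_dispersion_score(self, family, disp):
        fam = get_family(family)
        y = np.array([0.0, 1.0, 4.0])
        eta = np.array([-0.3, 0.4, 1.0])
        h = 1e-6
        fd = (
            fam.logpmf(y, eta, disp * math.exp(h))
            - fam.logpmf(y, eta, disp * math.exp(-h))
        ) / (2 * h)
        assert np.allclose(fam.score_logdisp(y, eta, disp), fd, atol=1e-5)


def test_nb_parameterization_roundtrip():
    # classical NB(r, p) mean maps onto the mean/dispersion form
    r, p = 2.0, 0.4
    mu = nb_mu_from_rp(r, p)
    assert mu == pytest.approx(r * (1 - p) / p)
    y = np.arange(12)
    ours = count_logpmf(y, math.log(mu), "negbin", r)
    assert np.allclose(ours, nbinom.logpmf(y, r, p), atol=1e-12)
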