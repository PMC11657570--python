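"""Two-level (cluster random-intercept) count regression models.

Respondents (level 1) are nested in clusters — cities in the motivating
survey (level 2).  The count part has linear predictor

    eta_ij = b_ij' beta + u_i,          u_i ~ N(0, sigma_u^2),

on the log scale of the family's rate parameter; for zero-inflated models
the structural-zero probability follows a logit model

    logit(phi_ij) = xi_ij = a_ij' alpha + w_i,   w_i ~ N(0, sigma_w^2),

with w and u independent.  The marginal likelihood integrates the random
intercepts out of each cluster's joint likelihood; the integral is
evaluated by adaptive Gauss-Hermite quadrature, i.e. the product rule is
centred at the per-cluster posterior mode of (w, u) and scaled by the local
curvature, so clusters with hundreds of observations (sharply peaked
integrands) are handled as accurately as tiny ones.  K = 1 reduces to the
Laplace approximation.

Estimation maximizes the marginal log-likelihood over
(beta, alpha, log dispersion, log sigma) with L-BFGS-B; gradients are
posterior-weighted score sums evaluated at the quadrature nodes.  Standard
errors come from the inverse observed information (finite differences of
the gradient at the optimum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats

from .cmp import CMPDivergenceError
from .design import DSCS_CODING, Coding, build_design
from .families import get_family

__all__ = [
    "ModelSpec",
    "TwoLevelCountModel",
    "TwoLevelCountResults",
    "cluster_marginal_loglik",
    "total_loglik",
    "fit_model",
    "significance_tier",
]

_LOG_2PI = np.log(2.0 * np.pi)
_SIGMA_FLOOR = 1e-10
_PENALTY = -1e12


@dataclass(frozen=True)
class ModelSpec:
    """Which of the six models to fit.

    family : 'poisson' | 'negbin' | 'cmp'
    zero_inflated : add the logit structural-zero part (with its own random
        intercept) on top of the count part.
    count_covariates / zero_covariates : covariate names (per the coding) for
        each part; ``None`` means all covariates in the coding.
    """

    family: str = "poisson"
    zero_inflated: bool = False
    count_covariates: tuple | None = None
    zero_covariates: tuple | None = None

    @property
    def name(self) -> str:
        fam = {"poisson": "P", "negbin": "NB", "cmp": "CMP"}[self.family]
        return f"TL-ZI{fam}" if self.zero_inflated else f"TL-{fam}"


def significance_tier(p: float) -> str:
    """Footnote stars at the 0.05 / 0.01 / 0.001 levels."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


class TwoLevelCountModel:
    """Marginal-likelihood model for clustered, possibly zero-inflated counts.

    Parameters
    ----------
    endog : (n,) non-negative integer counts.
    exog_count : (n, p_c) count-part design matrix, intercept first.
    groups : (n,) cluster labels (any hashable type).
    exog_zero : (n, p_z) zero-part design matrix; required iff zero_inflated.
    family : count family name.
    zero_inflated : include the structural-zero mixture part.
    """

    def __init__(
        self,
        endog,
        exog_count,
        groups,
        exog_zero=None,
        family: str = "poisson",
        zero_inflated: bool = False,
        exog_count_names=None,
        exog_zero_names=None,
    ):
        y = np.asarray(endog)
        if y.ndim != 1 or y.size == 0:
            raise ValueError("endog must be a nonempty 1-D array")
        if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
            raise ValueError("endog must contain non-negative integers")
        Xc = np.atleast_2d(np.asarray(exog_count, dtype=float))
        if Xc.shape[0] != y.size:
            raise ValueError("exog_count row count does not match endog")
        groups = np.asarray(groups)
        if groups.shape[0] != y.size:
            raise ValueError("groups length does not match endog")
        self.zero_inflated = bool(zero_inflated)
        if self.zero_inflated:
            if exog_zero is None:
                raise ValueError("zero_inflated model requires exog_zero")
            Xz = np.atleast_2d(np.asarray(exog_zero, dtype=float))
            if Xz.shape[0] != y.size:
                raise ValueError("exog_zero row count does not match endog")
        else:
            Xz = None

        # sort by cluster so per-cluster sums are contiguous reduceat calls
        codes, self.group_labels = pd.factorize(groups, sort=True)
        order = np.argsort(codes, kind="stable")
        self._order = order
        self.endog = y[order].astype(np.int64)
        self._yf = self.endog.astype(float)
        self.exog_count = Xc[order]
        self.exog_zero = Xz[order] if Xz is not None else None
        self.group_codes = codes[order]
        self.n_groups = len(self.group_labels)
        self.cluster_starts = np.searchsorted(
            self.group_codes, np.arange(self.n_groups)
        )
        self.cluster_sizes = np.diff(
            np.append(self.cluster_starts, self.endog.size)
        )
        self.family = get_family(family)
        self.nobs = self.endog.size
        self.exog_count_names = list(
            exog_count_names
            if exog_count_names is not None
            else [f"x{j}" for j in range(Xc.shape[1])]
        )
        self.exog_zero_names = (
            list(exog_zero_names)
            if exog_zero_names is not None
            else ([f"z{j}" for j in range(Xz.shape[1])] if Xz is not None else [])
        )
        self._mode_cache = None
        self._zero_mask = self.endog == 0

    # ------------------------------------------------------------------ #
    # construction helpers
    # ------------------------------------------------------------------ #

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        spec: ModelSpec,
        response: str = "y",
        groups: str = "city_id",
        coding: Coding = DSCS_CODING,
    ) -> "TwoLevelCountModel":
        """Build from a labelled survey frame using treatment coding."""
        Xc, names_c = build_design(df, coding, spec.count_covariates)
        if spec.zero_inflated:
            Xz, names_z = build_design(df, coding, spec.zero_covariates)
        else:
            Xz, names_z = None, None
        model = cls(
            df[response].to_numpy(),
            Xc,
            df[groups].to_numpy(),
            exog_zero=Xz,
            family=spec.family,
            zero_inflated=spec.zero_inflated,
            exog_count_names=names_c,
            exog_zero_names=names_z,
        )
        model.spec = spec
        return model

    # ------------------------------------------------------------------ #
    # parameter packing
    # ------------------------------------------------------------------ #

    @property
    def k_count(self) -> int:
        return self.exog_count.shape[1]

    @property
    def k_zero(self) -> int:
        return self.exog_zero.shape[1] if self.zero_inflated else 0

    @property
    def k_params(self) -> int:
        """Free parameters: both coefficient blocks, dispersion, RE SDs."""
        return (
            self.k_count
            + self.k_zero
            + (1 if self.family.has_dispersion else 0)
            + 1  # log sigma_u
            + (1 if self.zero_inflated else 0)  # log sigma_w
        )

    @property
    def param_names(self) -> list[str]:
        names = [f"count:{s}" for s in self.exog_count_names]
        if self.zero_inflated:
            names += [f"zero:{s}" for s in self.exog_zero_names]
        if self.family.has_dispersion:
            names += ["log_dispersion"]
        names += ["log_sigma_u"]
        if self.zero_inflated:
            names += ["log_sigma_w"]
        return names

    def _unpack(self, params):
        params = np.asarray(params, dtype=float)
        if params.size != self.k_params:
            raise ValueError(
                f"expected {self.k_params} parameters, got {params.size}"
            )
        i = self.k_count
        beta = params[:i]
        alpha = params[i : i + self.k_zero]
        i += self.k_zero
        disp = None
        if self.family.has_dispersion:
            disp = float(np.exp(params[i]))
            i += 1
        sigma_u = float(np.exp(params[i]))
        i += 1
        sigma_w = float(np.exp(params[i])) if self.zero_inflated else 0.0
        return beta, alpha, disp, sigma_u, sigma_w

    # ------------------------------------------------------------------ #
    # per-observation likelihood machinery
    # ------------------------------------------------------------------ #

    def _obs_terms(self, xi, eta, disp, need_scores=False, need_disp=False,
                   need_hess=False):
        """Per-observation ZI log-lik, scores, and curvature terms.

        ``xi`` may be None for a non-zero-inflated model.  All inputs may be
        (n,) or (n, K) arrays (quadrature nodes along the second axis).
        ``need_hess`` adds the second derivatives h_xi, h_eta, h_cross of
        the observation log-likelihood in (xi, eta), assembled from the
        family curvature and the mixture weights.
        """
        fam = self.family
        y = self._yf if np.ndim(eta) == 1 else self._yf[:, None]
        dargs = (disp,) if fam.has_dispersion else ()
        if fam.name in ("poisson", "negbin"):
            # cap the rate at exp(30): far outside any plausible region but
            # keeps trial steps of the optimizer free of overflow
            eta = np.minimum(eta, 30.0)
        if xi is not None:
            xi = np.clip(xi, -35.0, 35.0)
        kw = {}
        if fam.name == "cmp":
            # one series pass supplies logZ and all needed moments
            kw["stats"] = fam.prepare(
                eta, disp,
                need_mean=need_scores or need_hess,
                need_var=need_hess,
                need_elgam=need_disp,
            )
        if xi is None:
            ll = fam.logpmf(y, eta, *dargs, **kw)
            out = {"ll": ll}
            if need_scores:
                out["s_eta"] = fam.score_eta(y, eta, *dargs, **kw)
            if need_hess:
                out["h_eta"] = fam.d2_eta(y, eta, *dargs, **kw)
            if need_disp and fam.has_dispersion:
                out["s_disp"] = fam.score_logdisp(y, eta, *dargs, **kw)
            return out

        zero = self._zero_mask if np.ndim(eta) == 1 else self._zero_mask[:, None]
        # stable logistic pieces: log(phi), log(1 - phi)
        log_phi = -np.logaddexp(0.0, -xi)
        log_1mphi = -np.logaddexp(0.0, xi)
        logf = fam.logpmf(y, eta, *dargs, **kw)
        ll_pos = log_1mphi + logf
        logf0 = fam.logp0(eta, *dargs, **kw)
        mix = np.logaddexp(log_phi, log_1mphi + logf0)
        ll = np.where(zero, mix, ll_pos)
        out = {"ll": ll}
        if need_scores or need_disp or need_hess:
            phi = np.exp(log_phi)
            # posterior probability the zero is structural
            p_struct = np.exp(log_phi - mix)
            out["s_xi"] = np.where(zero, p_struct - phi, -phi)
            s0 = fam.score_eta0(eta, *dargs, **kw)
            s_eta_pos = fam.score_eta(y, eta, *dargs, **kw)
            out["s_eta"] = np.where(zero, (1.0 - p_struct) * s0, s_eta_pos)
            if need_hess:
                pq = p_struct * (1.0 - p_struct)
                h_xi_zero = -phi * (1.0 - phi) + pq
                h0 = fam.d2_eta0(eta, *dargs, **kw)
                h_eta_zero = (1.0 - p_struct) * h0 + pq * s0**2
                out["h_xi"] = np.where(zero, h_xi_zero, -phi * (1.0 - phi))
                out["h_eta"] = np.where(
                    zero, h_eta_zero, fam.d2_eta(y, eta, *dargs, **kw)
                )
                out["h_cross"] = np.where(zero, -pq * s0, 0.0)
            if need_disp and fam.has_dispersion:
                sd_pos = fam.score_logdisp(y, eta, *dargs, **kw)
                sd_zero = (1.0 - p_struct) * fam.score_logdisp0(eta, *dargs, **kw)
                out["s_disp"] = np.where(zero, sd_zero, sd_pos)
        return out

    def _cluster_sum(self, arr):
        return np.add.reduceat(arr, self.cluster_starts, axis=0)

    # ------------------------------------------------------------------ #
    # conditional (random effects fixed) likelihood — also stage-1 objective
    # ------------------------------------------------------------------ #

    def conditional_loglik(self, beta, alpha, disp, W=None, U=None):
        """Sum of observation log-likelihoods at fixed random effects."""
        eta = self.exog_count @ beta
        if U is not None:
            eta = eta + U[self.group_codes]
        xi = None
        if self.zero_inflated:
            xi = self.exog_zero @ alpha
            if W is not None:
                xi = xi + W[self.group_codes]
        return float(self._obs_terms(xi, eta, disp)["ll"].sum())

    # ------------------------------------------------------------------ #
    # posterior modes of the random effects (damped Newton, vectorized)
    # ------------------------------------------------------------------ #

    def _penalized(self, xb_c, xb_z, disp, sigma_u, sigma_w, W, U,
                   need_scores=False, need_hess=False):
        eta = xb_c + U[self.group_codes]
        xi = xb_z + W[self.group_codes] if self.zero_inflated else None
        terms = self._obs_terms(
            xi, eta, disp, need_scores=need_scores, need_hess=need_hess
        )
        F = self._cluster_sum(terms["ll"]) - 0.5 * (U / sigma_u) ** 2
        if self.zero_inflated:
            F = F - 0.5 * (W / sigma_w) ** 2
        out = {"F": F}
        if need_scores:
            out["Gu"] = self._cluster_sum(terms["s_eta"]) - U / sigma_u**2
            if self.zero_inflated:
                out["Gw"] = self._cluster_sum(terms["s_xi"]) - W / sigma_w**2
        if need_hess:
            out["Huu"] = self._cluster_sum(terms["h_eta"]) - 1.0 / sigma_u**2
            if self.zero_inflated:
                out["Hww"] = self._cluster_sum(terms["h_xi"]) - 1.0 / sigma_w**2
                out["Hwu"] = self._cluster_sum(terms["h_cross"])
        return out

    @staticmethod
    def _newton_step(cur, zi, m):
        """Per-cluster Newton direction from the analytic curvature."""
        Gu = cur["Gu"]
        Huu = np.minimum(cur["Huu"], -1e-8)
        if zi:
            Gw = cur["Gw"]
            Hww = np.minimum(cur["Hww"], -1e-8)
            Hcross = cur["Hwu"]
            det = Huu * Hww - Hcross**2
            bad = det <= 1e-12 * np.abs(Huu * Hww)
            Hcross = np.where(bad, 0.0, Hcross)
            det = Huu * Hww - Hcross**2
            dW = -(Huu * Gw - Hcross * Gu) / det
            dU = -(Hww * Gu - Hcross * Gw) / det
        else:
            dU = -Gu / Huu
            dW = np.zeros(m)
        return dW, dU

    def _find_modes(self, xb_c, xb_z, disp, sigma_u, sigma_w, max_iter=40):
        """Per-cluster mode and curvature of the penalized log-likelihood.

        Damped Newton with analytic per-cluster gradient and Hessian,
        warm-started from the previous call.  Returns (W, U, H) with H the
        (m, d, d) negative-definite Hessian of the penalized objective at
        the mode (d = 2 for ZI models, else 1 with the w slot absent).
        """
        m = self.n_groups
        zi = self.zero_inflated
        if self._mode_cache is not None:
            W, U = self._mode_cache
            W, U = W.copy(), U.copy()
        else:
            W = np.zeros(m)
            U = np.zeros(m)
        if not zi:
            W = np.zeros(m)

        cur = self._penalized(xb_c, xb_z, disp, sigma_u, sigma_w, W, U,
                              need_scores=True, need_hess=True)
        gtol = 1e-8 * max(1.0, self.nobs / m)
        for _ in range(max_iter):
            gmax = np.max(np.abs(cur["Gu"]))
            if zi:
                gmax = max(gmax, np.max(np.abs(cur["Gw"])))
            if gmax < gtol:
                break
            dW, dU = self._newton_step(cur, zi, m)
            # per-cluster backtracking on the penalized objective; NaN in a
            # trial objective counts as "worse"
            step = np.ones(m)
            F0 = cur["F"]
            for _ in range(12):
                Wn = W + step * dW
                Un = U + step * dU
                trial = self._penalized(xb_c, xb_z, disp, sigma_u, sigma_w, Wn, Un)
                worse = ~(trial["F"] >= F0 - 1e-12)
                if not np.any(worse):
                    break
                step = np.where(worse, step * 0.5, step)
            else:
                # clusters that never improved keep their previous state
                Wn = np.where(worse, W, Wn)
                Un = np.where(worse, U, Un)
            W, U = Wn, Un
            cur = self._penalized(xb_c, xb_z, disp, sigma_u, sigma_w, W, U,
                                  need_scores=True, need_hess=True)

        Huu = np.minimum(cur["Huu"], -1e-8)
        if zi:
            Hww = np.minimum(cur["Hww"], -1e-8)
            Hcross = cur["Hwu"]
            det = Huu * Hww - Hcross**2
            Hcross = np.where(det <= 1e-12 * np.abs(Huu * Hww), 0.0, Hcross)
            H = np.empty((m, 2, 2))
            H[:, 0, 0] = Hww
            H[:, 0, 1] = H[:, 1, 0] = Hcross
            H[:, 1, 1] = Huu
        else:
            H = Huu.reshape(m, 1, 1)
        self._mode_cache = (W.copy(), U.copy())
        return W, U, H

    # ------------------------------------------------------------------ #
    # adaptive Gauss-Hermite marginal likelihood and its gradient
    # ------------------------------------------------------------------ #

    def _quadrature(self, params, K=15, need_scores=False):
        beta, alpha, disp, sigma_u, sigma_w = self._unpack(params)
        sigma_u = max(sigma_u, _SIGMA_FLOOR)
        sigma_w = max(sigma_w, _SIGMA_FLOOR)
        zi = self.zero_inflated
        xb_c = self.exog_count @ beta
        xb_z = self.exog_zero @ alpha if zi else None

        W, U, H = self._find_modes(xb_c, xb_z, disp, sigma_u, sigma_w)
        m = self.n_groups

        z1, wq1 = hermgauss(K)
        logw1 = np.log(wq1)
        if zi:
            # product rule over (w, u); covariance scaling via 2x2 Cholesky
            Zw = np.repeat(z1, K)
            Zu = np.tile(z1, K)
            logw = np.add.outer(logw1, logw1).ravel()
            z2 = Zw**2 + Zu**2
            Sww = -H[:, 1, 1] / (H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2)
            Suu = -H[:, 0, 0] / (H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2)
            Swu = H[:, 0, 1] / (H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2)
            L11 = np.sqrt(Sww)
            L21 = Swu / L11
            L22 = np.sqrt(np.maximum(Suu - L21**2, 1e-300))
            w_nodes = W[:, None] + np.sqrt(2.0) * L11[:, None] * Zw[None, :]
            u_nodes = U[:, None] + np.sqrt(2.0) * (
                L21[:, None] * Zw[None, :] + L22[:, None] * Zu[None, :]
            )
            logdetL = np.log(L11) + np.log(L22)
            d = 2
        else:
            u_nodes = U[:, None] + np.sqrt(2.0) * np.sqrt(-1.0 / H[:, 0, 0])[:, None] * z1[None, :]
            w_nodes = None
            logw = logw1
            z2 = z1**2
            logdetL = 0.5 * np.log(-1.0 / H[:, 0, 0])
            d = 1

        eta = xb_c[:, None] + u_nodes[self.group_codes]
        xi = xb_z[:, None] + w_nodes[self.group_codes] if zi else None
        terms = self._obs_terms(
            xi, eta, disp, need_scores=need_scores, need_disp=need_scores
        )
        S = self._cluster_sum(terms["ll"])  # (m, Knodes)

        A = S - 0.5 * _LOG_2PI - np.log(sigma_u) - 0.5 * (u_nodes / sigma_u) ** 2
        if zi:
            A = A - 0.5 * _LOG_2PI - np.log(sigma_w) - 0.5 * (w_nodes / sigma_w) ** 2
        A = A + z2[None, :] + logw[None, :]

        Amax = A.max(axis=1)
        expA = np.exp(A - Amax[:, None])
        sumA = expA.sum(axis=1)
        cluster_ll = Amax + np.log(sumA) + 0.5 * d * np.log(2.0) + logdetL
        out = {
            "cluster_ll": cluster_ll,
            "loglik": float(cluster_ll.sum()),
            "modes": (W, U),
        }
        if need_scores:
            rho = expA / sumA[:, None]  # posterior node weights per cluster
            Wobs = rho[self.group_codes]
            g = np.empty(self.k_params)
            i = 0
            gc = (Wobs * terms["s_eta"]).sum(axis=1)
            g[: self.k_count] = self.exog_count.T @ gc
            i = self.k_count
            if zi:
                gz = (Wobs * terms["s_xi"]).sum(axis=1)
                g[i : i + self.k_zero] = self.exog_zero.T @ gz
                i += self.k_zero
            if self.family.has_dispersion:
                g[i] = float((Wobs * terms["s_disp"]).sum())
                i += 1
            g[i] = float((rho * ((u_nodes / sigma_u) ** 2 - 1.0)).sum())
            i += 1
            if zi:
                g[i] = float((rho * ((w_nodes / sigma_w) ** 2 - 1.0)).sum())
            out["score"] = g
        return out

    def loglike(self, params, K: int = 15) -> float:
        """Marginal log-likelihood (random effects integrated out)."""
        try:
            return self._quadrature(params, K=K)["loglik"]
        except (CMPDivergenceError, FloatingPointError):
            return _PENALTY

    def score(self, params, K: int = 15) -> np.ndarray:
        """Gradient of :meth:`loglike` (posterior-weighted scores)."""
        try:
            return self._quadrature(params, K=K, need_scores=True)["score"]
        except (CMPDivergenceError, FloatingPointError):
            return np.zeros(self.k_params)

    # ------------------------------------------------------------------ #
    # fitting
    # ------------------------------------------------------------------ #

    def _start_params(self):
        y = self._yf
        pos = y > 0
        beta = np.zeros(self.k_count)
        mean_pos = y[pos].mean() if pos.any() else 0.5
        if self.zero_inflated:
            beta[0] = np.log(max(mean_pos, 0.1))
            alpha = np.zeros(self.k_zero)
            zfrac = np.clip(1.0 - pos.mean(), 0.02, 0.98)
            alpha[0] = np.log(zfrac / (1.0 - zfrac))
        else:
            beta[0] = np.log(max(y.mean(), 0.05))
            alpha = np.zeros(0)
        parts = [beta, alpha]
        if self.family.has_dispersion:
            parts.append([0.0])  # dispersion 1.0
        return np.concatenate([np.asarray(p, dtype=float) for p in parts])

    def _fixed_effects_fit(self, maxiter=300):
        """Stage 1: ignore clustering, fit fixed effects (+ dispersion) only."""
        x0 = self._start_params()
        k_fix = x0.size

        def negll(th):
            beta = th[: self.k_count]
            alpha = th[self.k_count : self.k_count + self.k_zero]
            disp = (
                float(np.exp(th[-1])) if self.family.has_dispersion else None
            )
            try:
                eta = self.exog_count @ beta
                xi = self.exog_zero @ alpha if self.zero_inflated else None
                t = self._obs_terms(xi, eta, disp, need_scores=True, need_disp=True)
                f = -t["ll"].sum()
                g = np.empty(k_fix)
                g[: self.k_count] = -(self.exog_count.T @ t["s_eta"])
                if self.zero_inflated:
                    g[self.k_count : self.k_count + self.k_zero] = -(
                        self.exog_zero.T @ t["s_xi"]
                    )
                if self.family.has_dispersion:
                    g[-1] = -t["s_disp"].sum()
                return f, g
            except (CMPDivergenceError, FloatingPointError):
                d = th - x0
                return 1e10 * (1.0 + d @ d), 2e10 * d

        bounds = [(-30, 30)] * (self.k_count + self.k_zero)
        if self.family.has_dispersion:
            # stage-1 nu is only a starting value; keep it away from the
            # near-geometric region where the series cap bites, since the
            # no-RE fit otherwise absorbs cluster heterogeneity into nu
            bounds.append((np.log(0.15), 8.0) if self.family.name == "cmp"
                          else (-8.0, 12.0))
        res = optimize.minimize(
            negll, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter},
        )
        return res.x

    def fit(
        self,
        K: int = 15,
        maxiter: int = 500,
        tol: float = 1e-4,
        start_params=None,
        starts: int = 1,
        seed: int = 0,
        re_variance_start: float = 0.1,
    ) -> "TwoLevelCountResults":
        """Maximize the marginal likelihood.

        Multi-stage starting values: a fixed-effects-only fit supplies the
        coefficient block, then the random-effect variances enter at
        ``re_variance_start``.  ``starts > 1`` adds jittered restarts; ties
        are broken by highest log-likelihood, then smallest gradient norm.
        """
        if self.n_groups < 2:
            warnings.warn("fewer than 2 clusters: random-effect SD poorly identified")
        if start_params is None:
            fx = self._fixed_effects_fit()
            tail = [0.5 * np.log(re_variance_start)]
            if self.zero_inflated:
                tail.append(0.5 * np.log(re_variance_start))
            x0 = np.concatenate([fx, tail])
        else:
            x0 = np.asarray(start_params, dtype=float)

        # the start must itself be evaluable under quadrature; if the stage-1
        # dispersion is so extreme that the spread of the quadrature nodes
        # breaks the series/rate evaluations, relax it toward 1 stepwise
        if self.family.has_dispersion:
            disp_idx = self.k_count + self.k_zero
            for _ in range(12):
                self._mode_cache = None
                try:
                    if np.isfinite(self._quadrature(x0, K=K)["loglik"]):
                        break
                except (CMPDivergenceError, FloatingPointError):
                    pass
                x0[disp_idx] *= 0.5
                x0[: self.k_count] *= 0.9

        bounds = [(-30, 30)] * (self.k_count + self.k_zero)
        if self.family.has_dispersion:
            bounds.append((-3.5, 8.0) if self.family.name == "cmp" else (-8.0, 12.0))
        bounds.append((np.log(1e-6), 3.0))
        if self.zero_inflated:
            bounds.append((np.log(1e-6), 3.0))

        best_eval = {"f": np.inf, "x": None}

        def negll(th):
            # mode cache persists across evaluations (warm-started Newton)
            try:
                q = self._quadrature(th, K=K, need_scores=True)
                if not np.isfinite(q["loglik"]):
                    raise FloatingPointError("non-finite marginal likelihood")
                f = -q["loglik"]
                if f < best_eval["f"]:
                    best_eval["f"] = f
                    best_eval["x"] = th.copy()
                return f, -q["score"]
            except (CMPDivergenceError, FloatingPointError, np.linalg.LinAlgError):
                # quadratic penalty pulling back toward the start point, so
                # the optimizer retreats from a non-evaluable region instead
                # of stalling on a flat plateau
                self._mode_cache = None
                d = th - x0
                return 1e6 * (1.0 + d @ d), 2e6 * d

        rng = np.random.default_rng(seed)
        candidates = [x0]
        for _ in range(max(0, starts - 1)):
            jit = x0 + rng.normal(scale=0.2, size=x0.size)
            candidates.append(jit)

        best = None
        for cand in candidates:
            self._mode_cache = None
            res = optimize.minimize(
                negll, cand, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
            )
            if best_eval["x"] is not None and best_eval["f"] < res.fun - 1e-8:
                # the optimizer strayed into a non-evaluable region and gave
                # up there; restart from the best point actually evaluated
                self._mode_cache = None
                res = optimize.minimize(
                    negll, best_eval["x"], jac=True, method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
                )
            gnorm = float(np.max(np.abs(res.jac)))
            key = (-res.fun, -gnorm)
            if best is None or key > best[0]:
                best = (key, res, gnorm)
        _, res, gnorm = best

        llf = -float(res.fun)
        grad_scale = max(1.0, abs(llf))
        converged = bool(np.isfinite(llf)) and (gnorm < tol * grad_scale)
        try:
            q = self._quadrature(res.x, K=K)
        except (CMPDivergenceError, FloatingPointError):
            converged = False
            q = {"modes": (np.zeros(self.n_groups), np.zeros(self.n_groups))}
        return TwoLevelCountResults(
            self, res.x, llf, converged, gnorm, K, eb_modes=q["modes"],
            optim_result=res,
        )


class TwoLevelCountResults:
    """Estimates, uncertainties and diagnostics for a fitted two-level model.

    ``params`` is on the optimization scale (dispersion and random-effect
    SDs as logs); convenience accessors return natural-scale values.
    """

    def __init__(self, model, params, llf, converged, grad_norm, K, eb_modes,
                 optim_result=None):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.grad_norm = float(grad_norm)
        self.K = int(K)
        self.eb_modes = eb_modes
        self.optim_result = optim_result
        self._vcov = None
        self.vcov_singular = False
        beta, alpha, disp, sigma_u, sigma_w = model._unpack(self.params)
        self.beta = beta
        self.alpha = alpha
        self.dispersion = disp
        self.sigma_u = sigma_u
        self.sigma_w = sigma_w if model.zero_inflated else None

    # -- uncertainty ----------------------------------------------------- #

    @property
    def n_params(self) -> int:
        return self.model.k_params

    def cov_params(self, step: float = 1e-5) -> np.ndarray:
        """Inverse observed information via central differences of the score."""
        if self._vcov is not None:
            return self._vcov
        model = self.model
        k = self.n_params
        Hess = np.empty((k, k))
        for j in range(k):
            dp = np.zeros(k)
            dp[j] = step
            gp = model.score(self.params + dp, K=self.K)
            gm = model.score(self.params - dp, K=self.K)
            Hess[:, j] = (gp - gm) / (2.0 * step)
        Hess = 0.5 * (Hess + Hess.T)
        info = -Hess
        try:
            self._vcov = np.linalg.inv(info)
            if np.any(np.diag(self._vcov) <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
        except np.linalg.LinAlgError:
            warnings.warn(
                "observed information is singular (parameter at boundary?); "
                "standard errors use a pseudo-inverse and may be unreliable"
            )
            self.vcov_singular = True
            self._vcov = np.linalg.pinv(info)
        return self._vcov

    @property
    def bse(self) -> np.ndarray:
        d = np.diag(self.cov_params())
        return np.sqrt(np.clip(d, 0.0, None))

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    # -- fitted values --------------------------------------------------- #

    def fitted(self, conditional: bool = True) -> np.ndarray:
        """Fitted means, in the original row order of the input data.

        conditional=True plugs in the empirical-Bayes modes of the random
        effects; False sets them to zero (marginal-at-mode means).
        """
        model = self.model
        W, U = self.eb_modes
        eta = model.exog_count @ self.beta
        if conditional:
            eta = eta + U[model.group_codes]
        fam = model.family
        dargs = (self.dispersion,) if fam.has_dispersion else ()
        mu = fam.mean(eta, *dargs)
        if model.zero_inflated:
            xi = model.exog_zero @ self.alpha
            if conditional:
                xi = xi + W[model.group_codes]
            phi = 1.0 / (1.0 + np.exp(-xi))
            mu = (1.0 - phi) * mu
        out = np.empty_like(mu)
        out[model._order] = mu  # back to input order
        return out

    @property
    def random_effects(self) -> pd.DataFrame:
        W, U = self.eb_modes
        data = {"cluster": list(self.model.group_labels), "u_mode": U}
        if self.model.zero_inflated:
            data["w_mode"] = W
        return pd.DataFrame(data)

    # -- reporting -------------------------------------------------------- #

    def summary(self) -> str:
        model = self.model
        names = model.param_names
        se = self.bse
        pv = self.pvalues
        spec_name = getattr(model, "spec", None)
        title = spec_name.name if spec_name is not None else (
            ("TL-ZI" if model.zero_inflated else "TL-")
            + model.family.name.upper()
        )
        lines = [
            f"Two-level count model: {title}",
            f"  family={model.family.name}  zero_inflated={model.zero_inflated}",
            f"  nobs={model.nobs}  clusters={model.n_groups}  "
            f"K={self.K}  converged={self.converged}",
            f"  log-likelihood={self.llf:.3f}  n_params={self.n_params}",
            "",
            f"{'parameter':<28}{'estimate':>12}{'SE':>11}{'z':>9}{'p':>10}  sig",
        ]
        for j, nm in enumerate(names):
            lines.append(
                f"{nm:<28}{self.params[j]:>12.5f}{se[j]:>11.5f}"
                f"{self.zvalues[j]:>9.2f}{pv[j]:>10.3g}  {significance_tier(pv[j])}"
            )
        lines.append("")
        if self.dispersion is not None:
            lines.append(f"  dispersion (natural scale): {self.dispersion:.4f}")
        lines.append(f"  sigma_u: {self.sigma_u:.4g}")
        if self.sigma_w is not None:
            lines.append(f"  sigma_w: {self.sigma_w:.4g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------- #
# functional wrappers
# ---------------------------------------------------------------------- #


def cluster_marginal_loglik(
    y,
    exog_count,
    beta,
    sigma_u,
    exog_zero=None,
    alpha=None,
    sigma_w=0.0,
    family="poisson",
    dispersion=None,
    zero_inflated=False,
    K=15,
):
    """Marginal log-likelihood of a single cluster.

    Integrates the cluster's random intercepts out of the joint likelihood
    with adaptive Gauss-Hermite quadrature; an SD of exactly zero drops that
    dimension (degenerate random effect), and with both SDs zero this is
    just the conditional log-likelihood at w = u = 0.
    """
    y = np.asarray(y)
    model = TwoLevelCountModel(
        y,
        exog_count,
        np.zeros(y.size, dtype=int),
        exog_zero=exog_zero,
        family=family,
        zero_inflated=zero_inflated,
    )
    beta = np.asarray(beta, dtype=float)
    alpha = np.asarray(alpha, dtype=float) if alpha is not None else np.zeros(0)
    if sigma_u == 0.0 and (not zero_inflated or sigma_w == 0.0):
        return model.conditional_loglik(beta, alpha, dispersion)
    parts = [beta, alpha]
    if model.family.has_dispersion:
        parts.append([np.log(dispersion)])
    parts.append([np.log(max(sigma_u, _SIGMA_FLOOR))])
    if zero_inflated:
        parts.append([np.log(max(sigma_w, _SIGMA_FLOOR))])
    params = np.concatenate([np.asarray(p, dtype=float) for p in parts])
    q = model._quadrature(params, K=K)
    if not np.isfinite(q["loglik"]):
        raise FloatingPointError("non-finite marginal likelihood for cluster")
    return q["loglik"]


def total_loglik(df, spec: ModelSpec, params, K=15, coding=DSCS_CODING,
                 response="y", groups="city_id") -> float:
    """Marginal log-likelihood of a full dataset under ``spec`` at ``params``."""
    model = TwoLevelCountModel.from_dataframe(
        df, spec, response=response, groups=groups, coding=coding
    )
    return model.loglike(np.asarray(params, dtype=float), K=K)


def fit_model(df, spec: ModelSpec, K=15, coding=DSCS_CODING, response="y",
              groups="city_id", **fit_kw) -> TwoLevelCountResults:
    """Fit one of the six two-level models to a labelled survey frame."""
    model = TwoLevelCountModel.from_dataframe(
        df, spec, response=response, groups=groups, coding=coding
    )
    return model.fit(K=K, **fit_kw)
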