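"""Conway-Maxwell-Poisson (CMP) distribution.

The CMP distribution generalizes the Poisson with a second, dispersion
parameter ``nu``:

    P(Y = y | lam, nu) = lam**y / (y!)**nu / Z(lam, nu),
    Z(lam, nu) = sum_{i>=0} lam**i / (i!)**nu.

``nu = 1`` recovers the Poisson distribution with mean ``lam``; ``nu`` in
[0, 1) gives over-dispersion (variance above the mean) and ``nu > 1``
under-dispersion.  At ``nu = 0`` the series is geometric and converges only
for ``lam < 1``.

The normalizing constant Z has no closed form, so everything here is built
on a truncated series evaluated in log space (a streaming log-sum-exp over
terms ``i*log(lam) - nu*log(i!)``), which keeps the arithmetic finite even
when ``lam**i`` or ``(i!)**nu`` would overflow.  The truncation rule stops
once terms are decreasing and the current term is below ``rel_tol`` times
the running sum; terms start to decay after ``i > lam**(1/nu)``, so the
neglected tail is geometrically bounded.  A hard cap on the number of terms
turns a (near-)divergent series into an explicit error instead of a hang.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "CMPParams",
    "CMPDivergenceError",
    "cmp_log_normalizer",
    "cmp_logpmf",
    "cmp_pmf_table",
    "cmp_moments",
    "cmp_cdf",
    "cmp_ppf",
    "cmp_sample",
    "cmp_series_stats",
]

MAX_TERMS = 1_000_000
_BLOCK = 128


class CMPDivergenceError(ValueError):
    """The CMP normalizing series diverges or did not converge under the cap."""


@dataclass(frozen=True)
class CMPParams:
    """Validated (lam, nu) parameter pair.

    lam : rate-like parameter, > 0
    nu  : dispersion parameter, >= 0; nu == 0 requires lam < 1 (geometric
          boundary case), otherwise the normalizing series diverges.
    """

    lam: float
    nu: float

    def __post_init__(self) -> None:
        lam = float(self.lam)
        nu = float(self.nu)
        if not (math.isfinite(lam) and math.isfinite(nu)):
            raise ValueError(f"CMP parameters must be finite, got lam={lam}, nu={nu}")
        if lam <= 0:
            raise ValueError(f"CMP requires lam > 0, got {lam}")
        if nu < 0:
            raise ValueError(f"CMP requires nu >= 0, got {nu}")
        if nu == 0 and lam >= 1:
            raise CMPDivergenceError(
                f"CMP series diverges for nu=0 with lam={lam} >= 1"
            )
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "nu", nu)


def cmp_series_stats(
    log_lam,
    nu: float,
    rel_tol: float = 1e-12,
    max_terms: int = MAX_TERMS,
    need_mean: bool = False,
    need_var: bool = False,
    need_elgam: bool = False,
):
    """Truncated-series sufficient statistics for an array of log(lam) values.

    Returns a dict with ``logz`` and, on request, ``mean`` (E[Y]), ``var``
    (Var[Y]) and ``elgam`` (E[log Y!], needed for derivatives in nu).  All
    entries share the common dispersion ``nu``.  Entirely log-space; the
    only exponentiations are of already-centred quantities.
    """
    log_lam = np.asarray(log_lam, dtype=float)
    scalar = log_lam.ndim == 0
    shape = log_lam.shape
    ll = np.atleast_1d(log_lam).ravel()
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite log(lam) in CMP series")
    if not (0 < rel_tol <= 1e-6):
        raise ValueError(f"rel_tol must be in (0, 1e-6], got {rel_tol}")
    if nu < 0:
        raise ValueError(f"nu must be >= 0, got {nu}")
    if nu == 0 and np.any(ll >= 0):
        raise CMPDivergenceError("CMP series diverges for nu=0 with lam >= 1")

    if nu > 0:
        # Terms peak near i = lam**(1/nu); if that already exceeds the term
        # cap the truncated sum cannot represent Z, so fail fast instead of
        # summing a hopeless series.
        if float(np.max(ll)) / nu > math.log(max_terms):
            raise CMPDivergenceError(
                f"CMP series needs more than {max_terms} terms "
                f"(nu={nu}, max log_lam={float(np.max(ll)):.3g})"
            )

    n = ll.size
    want_mean = need_mean or need_var
    # Streaming scaled sums: S* hold sums of exp(t_i - M) so a single exp
    # per block feeds Z and all requested moments; M is the running peak.
    M = np.full(n, -np.inf)
    S0 = np.zeros(n)
    S1 = np.zeros(n) if want_mean else None
    S2 = np.zeros(n) if need_var else None
    Sg = np.zeros(n) if need_elgam else None

    active = np.arange(n)
    log_rel_tol = math.log(rel_tol)
    logz = np.empty(n)
    i0 = 0
    while active.size and i0 < max_terms:
        i = np.arange(i0, i0 + _BLOCK, dtype=float)
        lgam = gammaln(i + 1.0)
        t = ll[active, None] * i - nu * lgam  # (n_active, BLOCK)

        bmax = np.max(t, axis=1)
        newM = np.maximum(M[active], bmax)
        rescale = np.exp(M[active] - newM)
        E = np.exp(t - newM[:, None])
        S0[active] = S0[active] * rescale + E.sum(axis=1)
        if S1 is not None:
            S1[active] = S1[active] * rescale + E @ i
            if S2 is not None:
                S2[active] = S2[active] * rescale + E @ (i * i)
        if Sg is not None:
            Sg[active] = Sg[active] * rescale + E @ lgam
        M[active] = newM

        # converged once terms decrease and the last term is negligible
        # relative to the running sum
        with np.errstate(divide="ignore"):
            logz[active] = M[active] + np.log(S0[active])
        done = (t[:, -1] < t[:, -2]) & (t[:, -1] < logz[active] + log_rel_tol)
        active = active[~done]
        i0 += _BLOCK

    if active.size:
        raise CMPDivergenceError(
            f"CMP series did not converge within {max_terms} terms "
            f"(nu={nu}, max log_lam={ll[active].max():.3g})"
        )

    def _shape(a):
        return float(a[0]) if scalar else a.reshape(shape)

    out = {"logz": _shape(logz)}
    if want_mean:
        mean = S1 / S0
        out["mean"] = _shape(mean)
    if need_var:
        out["var"] = _shape(S2 / S0 - mean**2)
    if need_elgam:
        out["elgam"] = _shape(Sg / S0)
    return out


def cmp_log_normalizer(params: CMPParams, rel_tol: float = 1e-12) -> float:
    """log Z(lam, nu) with truncation tail below ``rel_tol`` of the sum."""
    return cmp_series_stats(math.log(params.lam), params.nu, rel_tol=rel_tol)["logz"]


def cmp_logpmf(y, params: CMPParams, rel_tol: float = 1e-12):
    """log P(Y = y); vectorized over ``y``."""
    y_arr = np.asarray(y)
    if np.any(y_arr < 0) or not np.all(np.equal(np.mod(y_arr, 1), 0)):
        raise ValueError("y must be a non-negative integer")
    yf = y_arr.astype(float)
    logz = cmp_log_normalizer(params, rel_tol=rel_tol)
    out = yf * math.log(params.lam) - params.nu * gammaln(yf + 1.0) - logz
    return float(out) if np.ndim(y) == 0 else out


def cmp_moments(params: CMPParams, rel_tol: float = 1e-12) -> tuple[float, float]:
    """(mean, variance) by the same truncated series as the normalizer."""
    st = cmp_series_stats(
        math.log(params.lam), params.nu, rel_tol=rel_tol, need_mean=True, need_var=True
    )
    return st["mean"], st["var"]


def cmp_pmf_table(params: CMPParams, tail_tol: float = 1e-12) -> np.ndarray:
    """pmf on 0..ymax where the neglected upper tail is below ``tail_tol``.

    ymax is found by extending the support until terms are decreasing and
    the accumulated probability reaches 1 - tail_tol of the normalizer.
    """
    logz = cmp_log_normalizer(params)
    log_lam = math.log(params.lam)
    nu = params.nu
    ymax = 64
    while ymax < MAX_TERMS:
        yy = np.arange(ymax + 1, dtype=float)
        logp = yy * log_lam - nu * gammaln(yy + 1.0) - logz
        pmf = np.exp(logp)
        if logp[-1] < logp[-2] and pmf.sum() >= 1.0 - tail_tol:
            return pmf
        ymax *= 2
    raise CMPDivergenceError("CMP support truncation failed to converge")


def cmp_cdf(y, params: CMPParams) -> float | np.ndarray:
    pmf = cmp_pmf_table(params)
    cdf = np.cumsum(pmf)
    y_arr = np.minimum(np.asarray(y, dtype=int), pmf.size - 1)
    out = cdf[y_arr]
    return float(out) if np.ndim(y) == 0 else out


def cmp_ppf(q, params: CMPParams) -> int | np.ndarray:
    """Smallest y with CDF(y) >= q (inverse CDF on the truncated support)."""
    pmf = cmp_pmf_table(params)
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0
    out = np.searchsorted(cdf, np.asarray(q), side="left")
    return int(out) if np.ndim(q) == 0 else out


def cmp_sample(params: CMPParams, n: int, seed) -> np.ndarray:
    """n i.i.d. draws by inverse-CDF over the truncated support.

    ``seed`` may be an int or a numpy Generator; an identical int seed
    reproduces the sequence exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pmf = cmp_pmf_table(params)
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0
    u = rng.random(int(n))
    return np.searchsorted(cdf, u, side="left").astype(np.int64)
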