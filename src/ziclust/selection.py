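"""Goodness-of-fit indices, model ranking and OR/RR effect tables.

The comparison indices are the conventional likelihood-based ones:

    D   = -2 LL                 (deviance, as reported for these models)
    AIC = -2 LL + 2 P
    BIC = -2 LL + P ln(n)       (n = number of observations, not clusters)
    MSE = (1/n) sum (y_ij - yhat_ij)^2

with P the number of free parameters and yhat the fitted mean, by default
conditional on the empirical-Bayes modes of the cluster random effects.

Effect tables exponentiate the coefficients: the odds ratio OR = exp(alpha_k)
multiplies the odds of a *structural zero* (a non-smoker) relative to the
reference level, and the rate ratio RR = exp(beta_k) multiplies the
count-part rate.  Reference levels carry OR = RR = 1 exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DSCS_CODING, Coding
from .model import TwoLevelCountResults, significance_tier

__all__ = [
    "FitIndices",
    "fit_indices",
    "rank_models",
    "effect_table",
    "percent_change",
]


@dataclass(frozen=True)
class FitIndices:
    """Comparison indices for one fitted model."""

    model: str
    P: int
    LL: float
    n_obs: int
    MSE: float | None = None
    dispersion: float | None = None
    converged: bool = True
    data_tag: str | None = None

    @property
    def D(self) -> float:
        return -2.0 * self.LL

    @property
    def AIC(self) -> float:
        return -2.0 * self.LL + 2.0 * self.P

    @property
    def BIC(self) -> float:
        return -2.0 * self.LL + self.P * np.log(self.n_obs)

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "P": self.P,
            "LL": self.LL,
            "n_obs": self.n_obs,
            "D": self.D,
            "AIC": self.AIC,
            "BIC": self.BIC,
            "MSE": self.MSE,
            "dispersion": self.dispersion,
            "converged": self.converged,
        }


def _data_tag(y: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(np.sort(y)).tobytes()).hexdigest()[:12]


def fit_indices(results: TwoLevelCountResults, conditional: bool = True) -> FitIndices:
    """Indices for one fit; MSE uses conditional (EB-mode) fitted means.

    ``conditional=False`` switches the MSE to marginal (random effects at
    zero) fitted means.
    """
    model = results.model
    y = np.empty(model.nobs)
    y[model._order] = model.endog  # original row order
    yhat = results.fitted(conditional=conditional)
    mse = float(np.mean((y - yhat) ** 2))
    name = getattr(model, "spec", None)
    return FitIndices(
        model=name.name if name is not None else model.family.name,
        P=results.n_params,
        LL=results.llf,
        n_obs=model.nobs,
        MSE=mse,
        dispersion=results.dispersion,
        converged=results.converged,
        data_tag=_data_tag(model.endog),
    )


def rank_models(indices) -> pd.DataFrame:
    """Rank fitted models on every index; overall winner by AIC, BIC tiebreak.

    Input fits must come from the same dataset (checked via a response
    fingerprint when available).  The returned frame carries one row per
    model with index values, per-index ranks, a ``winner`` flag and a
    ``rank_disagreement`` flag set when the indices do not all agree on the
    first place.
    """
    indices = list(indices)
    if not indices:
        raise ValueError("no fitted models to rank")
    tags = {ix.data_tag for ix in indices if ix.data_tag is not None}
    if len(tags) > 1:
        raise ValueError("cannot rank fits obtained on different datasets")

    rows = pd.DataFrame([ix.as_dict() for ix in indices])
    # all indices are better-smaller except LL
    rows["rank_LL"] = (-rows["LL"]).rank(method="min").astype(int)
    for col in ("D", "AIC", "BIC"):
        rows[f"rank_{col}"] = rows[col].rank(method="min").astype(int)
    if rows["MSE"].notna().all():
        rows["rank_MSE"] = rows["MSE"].rank(method="min").astype(int)

    order = rows.sort_values(["AIC", "BIC", "model"]).index
    winner = order[0]
    tie = len(rows) > 1 and np.isclose(
        rows.loc[order[0], "AIC"], rows.loc[order[1], "AIC"]
    )
    rows["winner"] = False
    rows.loc[winner, "winner"] = True
    rows["aic_tie_broken_by_bic"] = bool(tie)
    rank_cols = [c for c in rows.columns if c.startswith("rank_")]
    rows["rank_disagreement"] = bool(
        (rows.loc[winner, rank_cols] != 1).any() if rank_cols else False
    )
    return rows.sort_values("AIC").reset_index(drop=True)


def percent_change(rr: float) -> float:
    """Percent reduction implied by a rate ratio below 1: 100 (1 - RR)."""
    return 100.0 * (1.0 - rr)


def effect_table(results: TwoLevelCountResults, coding: Coding = DSCS_CODING) -> pd.DataFrame:
    """OR/RR effect table for a zero-inflated fit, one row per covariate level.

    Reference levels carry estimate 0 and OR = RR = 1 exactly.  Significance
    tiers star the Wald p-values at 0.05 / 0.01 / 0.001.
    """
    model = results.model
    if not model.zero_inflated:
        raise ValueError("effect table requires a zero-inflated fit (both parts)")
    names = model.param_names
    est = dict(zip(names, results.params))
    se = dict(zip(names, results.bse))
    pv = dict(zip(names, results.pvalues))

    cov_names = [
        c.name
        for c in coding.covariates
        if any(nm.startswith(f"count:{c.name}[") for nm in names)
    ]
    rows = []

    def _part(prefix, col):
        key = f"{prefix}:{col}"
        if key in est:
            return est[key], se[key], significance_tier(pv[key])
        return np.nan, np.nan, ""

    for cname in cov_names:
        cov = coding[cname]
        rows.append(
            {
                "variable": cname,
                "level": cov.reference,
                "reference": True,
                "zero_est": 0.0,
                "zero_se": np.nan,
                "zero_sig": "",
                "count_est": 0.0,
                "count_se": np.nan,
                "count_sig": "",
                "OR": 1.0,
                "RR": 1.0,
            }
        )
        for lv in cov.coded_levels:
            col = f"{cname}[{lv}]"
            ze, zs, zt = _part("zero", col)
            ce, cs, ct = _part("count", col)
            rows.append(
                {
                    "variable": cname,
                    "level": lv,
                    "reference": False,
                    "zero_est": ze,
                    "zero_se": zs,
                    "zero_sig": zt,
                    "count_est": ce,
                    "count_se": cs,
                    "count_sig": ct,
                    "OR": float(np.exp(ze)),
                    "RR": float(np.exp(ce)),
                }
            )
    return pd.DataFrame(rows)
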