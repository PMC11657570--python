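"""Descriptive tables and bivariate screening tests for survey count data.

A "smoker" is a respondent with a positive daily count at interview; past
smoking is not represented in the data.  The bivariate tests are reporting
conveniences (chi-square on smoker status, rank tests on the counts) and
never gate the modelling stages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .design import DSCS_CODING, Coding
from .synthetic import SEVERITY_LEVELS, severity

__all__ = ["city_summary", "group_summary", "variance_mean_ratio"]


def _severity_percents(y: np.ndarray) -> dict:
    sev = severity(y)
    n = y.size
    return {
        f"pct_{lv}": 100.0 * np.sum(sev == lv) / n for lv in SEVERITY_LEVELS[1:]
    }


def city_summary(df: pd.DataFrame, groups: str = "city_id",
                 response: str = "y") -> pd.DataFrame:
    """Per-city sizes, smoker shares by severity, and mean +/- SD counts.

    The ``Total`` row pools all respondents; its percentages equal the sums
    of the per-severity shares by construction.
    """
    if df.empty:
        raise ValueError("empty dataset")
    rows = []
    for city, g in df.groupby(groups, sort=False):
        y = g[response].to_numpy()
        rows.append(
            {
                "city": city,
                "n": y.size,
                "pct_smoker": 100.0 * np.mean(y > 0),
                **_severity_percents(y),
                "mean": float(y.mean()),
                "sd": float(y.std(ddof=1)) if y.size > 1 else np.nan,
            }
        )
    y = df[response].to_numpy()
    rows.append(
        {
            "city": "Total",
            "n": y.size,
            "pct_smoker": 100.0 * np.mean(y > 0),
            **_severity_percents(y),
            "mean": float(y.mean()),
            "sd": float(y.std(ddof=1)),
        }
    )
    return pd.DataFrame(rows)


def group_summary(df: pd.DataFrame, coding: Coding = DSCS_CODING,
                  response: str = "y") -> pd.DataFrame:
    """Per covariate level: n (%), mean (SD) counts, smoker split, tests.

    The chi-square test crosses smoker status with the covariate; the count
    distribution is compared across levels with a Mann-Whitney U test (two
    levels) or Kruskal-Wallis rank ANOVA (more), both with large-sample
    p-values.  Levels absent from the data are dropped with a warning.
    """
    if df.empty:
        raise ValueError("empty dataset")
    y = df[response].to_numpy()
    smoker = y > 0
    out = []
    for cov in coding.covariates:
        if cov.name not in df.columns:
            continue
        vals = df[cov.name].astype(str).to_numpy()
        levels = [lv for lv in cov.levels if np.any(vals == lv)]
        dropped = set(cov.levels) - set(levels)
        if dropped:
            warnings.warn(
                f"levels {sorted(dropped)} of {cov.name!r} have no observations"
            )
        groups = [y[vals == lv] for lv in levels]
        # chi-square: smoker status x covariate level
        table = np.array(
            [[np.sum(~smoker[vals == lv]), np.sum(smoker[vals == lv])]
             for lv in levels]
        )
        if len(levels) > 1 and table.sum(axis=0).min() > 0:
            chi2_p = float(stats.chi2_contingency(table)[1])
        else:
            chi2_p = np.nan
        if len(levels) == 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rank_p = float(
                    stats.mannwhitneyu(groups[0], groups[1]).pvalue
                    if min(len(g) for g in groups) > 0 else np.nan
                )
        elif len(levels) > 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    rank_p = float(stats.kruskal(*groups).pvalue)
                except ValueError:  # all values identical
                    rank_p = 1.0
        else:
            rank_p = np.nan
        for lv, g in zip(levels, groups):
            out.append(
                {
                    "variable": cov.name,
                    "level": lv,
                    "n": g.size,
                    "pct": 100.0 * g.size / y.size,
                    "mean": float(g.mean()),
                    "sd": float(g.std(ddof=1)) if g.size > 1 else np.nan,
                    "n_nonsmoker": int(np.sum(g == 0)),
                    "n_smoker": int(np.sum(g > 0)),
                    "chi2_p": chi2_p,
                    "rank_p": rank_p,
                }
            )
    return pd.DataFrame(out)


def variance_mean_ratio(y) -> float:
    """Sample variance / sample mean — the overdispersion screen.

    Accepts a count vector or a dataset frame with a ``y`` column.  Raises
    for all-zero data, where the ratio is undefined.
    """
    if isinstance(y, pd.DataFrame):
        y = y["y"]
    y = np.asarray(y, dtype=float)
    if y.size == 0 or np.all(y == 0):
        raise ValueError("variance/mean ratio undefined for all-zero data")
    return float(y.var(ddof=1) / y.mean())
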