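"""Categorical covariate coding for DSCS-style survey data.

Treatment (reference-level) coding: each categorical covariate contributes
one indicator column per non-reference level, and every design matrix
carries an intercept as its first column.  The default coding mirrors the
Daily Smoking Consumption Survey questionnaire — 12 covariates whose
non-reference levels add up to 23 columns, i.e. 24 fixed effects per model
part including the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Covariate", "Coding", "DSCS_CODING", "DSCS_COLUMNS", "build_design"]


@dataclass(frozen=True)
class Covariate:
    """One categorical covariate: column name and ordered levels.

    The first level is the reference and is absorbed into the intercept.
    """

    name: str
    levels: tuple[str, ...]

    @property
    def reference(self) -> str:
        return self.levels[0]

    @property
    def coded_levels(self) -> tuple[str, ...]:
        return self.levels[1:]


@dataclass(frozen=True)
class Coding:
    """An ordered collection of covariates defining a design matrix layout."""

    covariates: tuple[Covariate, ...]

    def __getitem__(self, name: str) -> Covariate:
        for cov in self.covariates:
            if cov.name == name:
                return cov
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    def subset(self, names) -> "Coding":
        return Coding(tuple(self[n] for n in names))

    def column_names(self) -> list[str]:
        cols = ["Intercept"]
        for cov in self.covariates:
            cols += [f"{cov.name}[{lv}]" for lv in cov.coded_levels]
        return cols

    @property
    def n_columns(self) -> int:
        return 1 + sum(len(c.coded_levels) for c in self.covariates)


_YN = ("No", "Yes")

DSCS_CODING = Coding(
    (
        Covariate("age_group", ("<=20", "21-25", "26-30", ">30")),
        Covariate("sex", ("Female", "Male")),
        Covariate(
            "bmi_class",
            ("Underweight", "Normal", "Overweight", "Obese", "Extremely obese"),
        ),
        Covariate("marital", ("Married", "Single")),
        Covariate(
            "education",
            ("Illiterate", "Elementary/Middle", "Diploma", "AD/BSc", "MSc/PhD"),
        ),
        Covariate(
            "occupation",
            (
                "Unemployed/student",
                "Organizational",
                "Freelance",
                "Agricultural/livestock",
                "Housewife",
            ),
        ),
        Covariate("residence", ("Rural", "Urban")),
        Covariate("disease_hist", _YN),
        Covariate("fam_mental", _YN),
        Covariate("fam_chronic", _YN),
        Covariate("general_study", _YN),
        Covariate("hookah", _YN),
    )
)

#: CSV column order for DSCS-style datasets.
DSCS_COLUMNS = ["city_id", "y"] + list(DSCS_CODING.names)


def build_design(
    df: pd.DataFrame, coding: Coding = DSCS_CODING, covariates=None
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix (intercept first) from labelled columns.

    Parameters
    ----------
    df : frame with one string-labelled column per covariate.
    coding : layout defining level order and references.
    covariates : optional subset (by name) of ``coding``'s covariates;
        defaults to all of them.

    Returns the (n, p) float matrix and the column names.
    """
    sub = coding if covariates is None else coding.subset(covariates)
    n = len(df)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for cov in sub.covariates:
        if cov.name not in df.columns:
            raise ValueError(f"missing covariate column {cov.name!r}")
        vals = df[cov.name].astype(str)
        unknown = set(vals.unique()) - set(cov.levels)
        if unknown:
            raise ValueError(f"unknown levels {sorted(unknown)} in {cov.name!r}")
        for lv in cov.coded_levels:
            cols.append((vals == lv).to_numpy(dtype=float))
            names.append(f"{cov.name}[{lv}]")
    return np.column_stack(cols), names
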