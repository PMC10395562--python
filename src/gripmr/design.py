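"""Covariate design-matrix builders shared by the analysis arms.

The observational arm adjusts for the exposure's established determinants
(calendar month of blood draw, vitamin D supplementation) plus potential
confounders (age, smoking status, BMI, Townsend deprivation).  The genetic
arm adjusts for the exposure determinants and genetic ancestry (10 principal
components) only — confounders are what the instrument is meant to bypass.
"""

from __future__ import annotations

import pandas as pd

from .exceptions import InsufficientDataError

__all__ = ["month_dummies", "observational_design", "mr_design", "subset_sex"]

SEXES = ("male", "female")


def subset_sex(cohort: pd.DataFrame, sex: str) -> pd.DataFrame:
    """Restrict a cohort to one sex (all analyses are sex-stratified)."""
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    sub = cohort.loc[cohort["sex"] == sex]
    if sub.empty:
        raise InsufficientDataError(f"no rows with sex == {sex!r}")
    return sub.reset_index(drop=True)


def month_dummies(month: pd.Series) -> pd.DataFrame:
    """Calendar month as 11 indicator columns (January is the reference)."""
    cat = pd.Categorical(month, categories=range(1, 13))
    out = pd.get_dummies(cat, prefix="month", drop_first=True).astype(float)
    out.index = month.index
    return out


def _smoking_dummies(smoking: pd.Series) -> pd.DataFrame:
    cat = pd.Categorical(smoking, categories=["never", "previous", "current"])
    out = pd.get_dummies(cat, prefix="smoking", drop_first=True).astype(float)
    out.index = smoking.index
    return out


def observational_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Covariate columns for the cross-sectional regression."""
    parts = [
        month_dummies(cohort["month"]),
        cohort[["supplement"]].astype(float),
        cohort[["age", "bmi", "townsend"]].astype(float),
        _smoking_dummies(cohort["smoking"]),
    ]
    out = pd.concat(parts, axis=1)
    out.index = cohort.index
    return out


def mr_design(cohort: pd.DataFrame, n_pcs: int = 10) -> pd.DataFrame:
    """Covariate columns for the genetic analyses: month, supplementation
    and the leading genetic principal components."""
    pcs = [f"pc{i + 1}" for i in range(n_pcs) if f"pc{i + 1}" in cohort.columns]
    parts = [
        month_dummies(cohort["month"]),
        cohort[["supplement"]].astype(float),
        cohort[pcs].astype(float),
    ]
    out = pd.concat(parts, axis=1)
    out.index = cohort.index
    return out
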