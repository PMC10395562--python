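"""Cross-sectional dose-response analysis of grip strength on 25(OH)D.

Sex-stratified, covariate-adjusted fractional-polynomial regression: the
best FP2 is compared against the best FP1 (LR test, 2 df) to fix the FP
degree, and the winning FP against the straight line (1 or 3 df) to test
nonlinearity (p < .05 favours the curved model).  The fitted model is
summarised as a mean-difference curve anchored at a reference exposure
(default 50 nmol/L).  An age-stratified variant refits the selected form in
four fixed age bands and tests age x exposure interaction by LR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import observational_design, subset_sex
from .exceptions import InsufficientDataError
from .fracpoly import (
    CausalCurve,
    FPFit,
    LRTestResult,
    _ols,
    compare_fp,
    curve_from_fp,
    fit_fp,
    fit_fp_fixed,
    fit_linear,
    fp_basis,
)

__all__ = [
    "AGE_BAND_LABELS",
    "assign_age_band",
    "ObservationalResult",
    "AgeStratifiedResult",
    "run_observational",
    "run_age_stratified",
]

#: Age bands: <50, 50-59, 60-64, 65+ (closed on the left, integer ages).
AGE_BAND_LABELS = ("<50", "50-59", "60-64", "65+")


def assign_age_band(age) -> np.ndarray:
    """Map ages to bands 1..4 (1: <50, 2: 50-59, 3: 60-64, 4: 65+)."""
    age = np.asarray(age)
    return np.select([age < 50, age <= 59, age <= 64], [1, 2, 3], default=4)


def default_grid() -> np.ndarray:
    """15-90 nmol/L in 1 nmol/L steps, covering the plotted exposure range."""
    return np.arange(15.0, 90.0 + 1.0, 1.0)


@dataclass
class ObservationalResult:
    """Output of the sex-specific cross-sectional analysis."""

    sex: str
    n: int
    fit: FPFit  # selected model (FP if nonlinear, else linear)
    linear_fit: FPFit
    fp1_fit: FPFit
    fp2_fit: FPFit
    lr_fp2_vs_fp1: LRTestResult
    p_nonlinear: LRTestResult  # best FP vs linear
    curve: CausalCurve


def run_observational(
    cohort: pd.DataFrame,
    sex: str,
    reference: float = 50.0,
    grid=None,
    min_n: int = 500,
    alpha: float = 0.05,
) -> ObservationalResult:
    """Covariate-adjusted FP dose-response analysis in one sex.

    Adjusts for month of blood draw (categorical), supplementation, age,
    smoking (categorical), BMI and Townsend score; selects between linear,
    best FP1 and best FP2 via the likelihood-ratio cascade and returns the
    reference-anchored mean-difference curve of the selected model.
    """
    sub = subset_sex(cohort, sex)
    if len(sub) < min_n:
        raise InsufficientDataError(
            f"{len(sub)} rows for sex={sex!r}, below the floor of {min_n}"
        )
    y = sub["outcome"].to_numpy(dtype=float)
    x = sub["exposure"].to_numpy(dtype=float)
    covs = observational_design(sub)
    linear = fit_linear(y, x, covs)
    fp1 = fit_fp(y, x, covs, degree=1)
    fp2 = fit_fp(y, x, covs, degree=2)
    lr21 = compare_fp(fp1, fp2)
    best_fp = fp2 if lr21.p < alpha else fp1
    p_nonlinear = compare_fp(linear, best_fp)
    selected = best_fp if p_nonlinear.p < alpha else linear
    if grid is None:
        grid = default_grid()
    curve = curve_from_fp(selected, reference=reference, grid=grid)
    return ObservationalResult(
        sex=sex,
        n=len(sub),
        fit=selected,
        linear_fit=linear,
        fp1_fit=fp1,
        fp2_fit=fp2,
        lr_fp2_vs_fp1=lr21,
        p_nonlinear=p_nonlinear,
        curve=curve,
    )


@dataclass
class AgeStratifiedResult:
    """Per-age-band dose-response curves and the interaction test."""

    sex: str
    powers: tuple[float, ...]
    band_fits: dict[str, FPFit]
    band_curves: dict[str, CausalCurve]
    interaction: LRTestResult


def run_age_stratified(
    cohort: pd.DataFrame,
    sex: str,
    reference: float = 50.0,
    grid=None,
    pooled: ObservationalResult | None = None,
) -> AgeStratifiedResult:
    """Refit the pooled sex-specific FP form within four fixed age bands.

    The exposure powers are those selected by the pooled analysis (not
    re-selected per band, keeping the interaction df interpretable).  The
    interaction test is an LR comparison of the pooled model with age-band
    main effects against the same model plus age-band x FP-term interaction
    columns (df = 3 x number of FP terms).  Continuous age stays in the
    covariate set within bands.
    """
    sub = subset_sex(cohort, sex)
    if pooled is None:
        pooled = run_observational(cohort, sex, reference=reference, grid=grid)
    powers = pooled.fit.powers
    if grid is None:
        grid = default_grid()
    band = assign_age_band(sub["age"])

    band_fits: dict[str, FPFit] = {}
    band_curves: dict[str, CausalCurve] = {}
    for b, label in enumerate(AGE_BAND_LABELS, start=1):
        rows = band == b
        if not rows.any():
            warnings.warn(f"age band {label} is empty; skipped", stacklevel=2)
            continue
        g = sub.loc[rows]
        fit = fit_fp_fixed(
            g["outcome"].to_numpy(float),
            g["exposure"].to_numpy(float),
            observational_design(g),
            powers=powers,
            family=pooled.fit.family,
        )
        band_fits[label] = fit
        band_curves[label] = curve_from_fp(fit, reference=reference, grid=grid)

    # interaction LR test on the pooled data
    y = sub["outcome"].to_numpy(float)
    x = sub["exposure"].to_numpy(float)
    covs = observational_design(sub).to_numpy(float)
    basis = fp_basis(x, powers)
    band_d = np.column_stack([(band == b).astype(float) for b in (2, 3, 4)])
    base_design = np.hstack([np.ones((len(y), 1)), basis, covs, band_d])
    inter = np.hstack([band_d[:, [k]] * basis for k in range(band_d.shape[1])])
    full_design = np.hstack([base_design, inter])
    _, _, _, dev0 = _ols(base_design, y)
    _, _, _, dev1 = _ols(full_design, y)
    df = 3 * basis.shape[1]
    statistic = max(dev0 - dev1, 0.0)
    interaction = LRTestResult(
        statistic=float(statistic), df=df, p=float(stats.chi2.sf(statistic, df))
    )
    return AgeStratifiedResult(
        sex=sex,
        powers=powers,
        band_fits=band_fits,
        band_curves=band_curves,
        interaction=interaction,
    )
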