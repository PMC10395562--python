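"""Fractional-polynomial regression machinery.

Fractional polynomials (FPs) model a continuous covariate x > 0 through powers
drawn from the canonical set S = {-2, -1, -0.5, 0, 0.5, 1, 2, 3}, with the
convention that power 0 denotes ln x and that a repeated power contributes an
extra ln x factor (so FP2 with powers (p, p) has basis x^p and x^p * ln x).
Degree-1 (FP1) and degree-2 (FP2) families are searched exhaustively, the
best model being the one with the smallest Gaussian deviance (-2 log
likelihood under OLS); ties go to the earlier model in enumeration order,
i.e. toward the simpler shape.

The same basis construction serves two roles in this package: direct
covariate-adjusted regression of grip strength on 25(OH)D, and (through the
derivative basis in :mod:`gripmr.nonlinear`) meta-regression of stratum-level
causal-effect estimates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .exceptions import DomainError, IncomparableFitsError, SingularFitError

__all__ = [
    "FP_POWERS",
    "FPFit",
    "LRTestResult",
    "CausalCurve",
    "fp_basis",
    "fp_power_sets",
    "fit_fp",
    "fit_fp_fixed",
    "fit_linear",
    "compare_fp",
    "curve_from_fp",
]

#: Canonical Royston-Altman power set; 0 stands for ln x.
FP_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

_FAMILY_RANK = {"linear": 0, "fp1": 1, "fp2": 2}

#: Degrees of freedom for likelihood-ratio comparisons between families
#: (Stata/Royston convention): FP1 vs linear 1, FP2 vs FP1 2, FP2 vs linear 3.
_LR_DF = {(0, 1): 1, (1, 2): 2, (0, 2): 3}


def _check_positive(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    bad = np.count_nonzero(~(x > 0))
    if bad:
        raise DomainError(
            f"fractional-polynomial basis requires x > 0; {bad} offending row(s)"
        )
    return x


def fp_basis(x, powers: Sequence[float]) -> np.ndarray:
    """Evaluate the FP basis columns for ``powers`` at ``x`` (> 0).

    Power p gives x**p, p = 0 gives ln x; the k-th repetition of a power
    multiplies its column by (ln x)**k.
    """
    x = _check_positive(np.atleast_1d(x))
    lnx = np.log(x)
    cols = []
    seen: dict[float, int] = {}
    for p in powers:
        p = float(p)
        k = seen.get(p, 0)
        seen[p] = k + 1
        base = lnx if p == 0.0 else x**p
        cols.append(base * lnx**k if k else base)
    return np.column_stack(cols)


def fp_derivative_basis(x, powers: Sequence[float]) -> np.ndarray:
    """d/dx of each :func:`fp_basis` column, in closed form.

    Used by the nonlinear-MR meta-regression, where stratum-level causal
    effects estimate the *slope* of the dose-response function.
    """
    x = _check_positive(np.atleast_1d(x))
    lnx = np.log(x)
    cols = []
    seen: dict[float, int] = {}
    for p in powers:
        p = float(p)
        k = seen.get(p, 0)
        seen[p] = k + 1
        if p == 0.0:
            # basis column is (ln x)^(k+1)
            d = (k + 1) * lnx**k / x
        elif k == 0:
            d = p * x ** (p - 1.0)
        else:
            d = x ** (p - 1.0) * (p * lnx**k + k * lnx ** (k - 1))
        cols.append(d)
    return np.column_stack(cols)


def fp_power_sets(degree: int) -> list[tuple[float, ...]]:
    """All candidate power tuples for an FP of the given degree, in the
    enumeration order used for tie-breaking."""
    if degree == 1:
        return [(p,) for p in FP_POWERS]
    if degree == 2:
        return list(itertools.combinations_with_replacement(FP_POWERS, 2))
    raise ValueError(f"degree must be 1 or 2, got {degree}")


@dataclass
class LRTestResult:
    """A likelihood-ratio test: chi-squared statistic, df and p-value."""

    statistic: float
    df: int
    p: float


@dataclass
class FPFit:
    """A fitted fractional-polynomial regression.

    ``coefficients``/``covariance`` cover the full design (intercept, FP
    terms, covariates); ``fp_index`` marks the FP-term positions so curve
    construction can form contrasts on the FP block only.  ``deviance`` is
    -2 log likelihood under Gaussian errors for OLS fits, and the weighted
    residual sum of squares (fixed, known variances) for meta-regression
    fits — comparable within a family of fits on the same data either way.
    """

    family: str  # linear | fp1 | fp2 | meta_linear | meta_fp1 | meta_fp2
    degree: int
    powers: tuple[float, ...]
    coefficients: np.ndarray
    covariance: np.ndarray
    deviance: float
    n: int
    fp_index: tuple[int, ...]
    column_names: tuple[str, ...] = field(default_factory=tuple)
    x_range: tuple[float, float] | None = None

    @property
    def fp_coefficients(self) -> np.ndarray:
        return self.coefficients[list(self.fp_index)]

    @property
    def fp_covariance(self) -> np.ndarray:
        idx = list(self.fp_index)
        return self.covariance[np.ix_(idx, idx)]


def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Least squares with Gaussian deviance.

    Returns (beta, covariance, rss, deviance).  The covariance uses the
    unbiased residual variance; the deviance is -2 times the Gaussian
    log-likelihood at the MLE, n*(log(2*pi*rss/n) + 1).
    """
    n, p = design.shape
    if n <= p:
        raise SingularFitError(f"{n} rows cannot identify {p} coefficients")
    gram = design.T @ design
    try:
        cf = sla.cho_factor(gram, check_finite=False)
    except (sla.LinAlgError, ValueError) as exc:
        raise SingularFitError("rank-deficient design matrix") from exc
    beta = sla.cho_solve(cf, design.T @ y, check_finite=False)
    resid = y - design @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    cov = sla.cho_solve(cf, np.eye(p), check_finite=False) * sigma2
    # guard against tiny negative rss from cancellation in exact-fit cases
    deviance = n * (np.log(2.0 * np.pi * max(rss, 1e-300) / n) + 1.0)
    return beta, cov, rss, deviance


def _as_matrix(covariates) -> tuple[np.ndarray | None, tuple[str, ...]]:
    if covariates is None:
        return None, ()
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), tuple(map(str, covariates.columns))
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, tuple(f"cov{i}" for i in range(arr.shape[1]))


def fit_fp_fixed(
    y,
    x,
    covariates=None,
    powers: Sequence[float] = (1.0,),
    family: str | None = None,
) -> FPFit:
    """OLS fit of y on the FP basis of x for the given powers, plus an
    intercept and optional covariate columns."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("y and x lengths differ")
    basis = fp_basis(x, powers)
    cmat, cnames = _as_matrix(covariates)
    if cmat is not None and cmat.shape[0] != y.shape[0]:
        raise ValueError("covariate rows do not match y")
    blocks = [np.ones((y.shape[0], 1)), basis]
    names = ["const"] + [f"fp{i}" for i in range(basis.shape[1])]
    if cmat is not None:
        blocks.append(cmat)
        names.extend(cnames)
    design = np.hstack(blocks)
    beta, cov, _, deviance = _ols(design, y)
    powers = tuple(float(p) for p in powers)
    if family is None:
        family = "fp1" if len(powers) == 1 else "fp2"
    return FPFit(
        family=family,
        degree=len(powers),
        powers=powers,
        coefficients=beta,
        covariance=cov,
        deviance=deviance,
        n=int(y.shape[0]),
        fp_index=tuple(range(1, 1 + basis.shape[1])),
        column_names=tuple(names),
        x_range=(float(np.min(x)), float(np.max(x))),
    )


def fit_linear(y, x, covariates=None) -> FPFit:
    """The straight-line model, i.e. the FP family member with power 1."""
    return fit_fp_fixed(y, x, covariates, powers=(1.0,), family="linear")


def fit_fp(y, x, covariates=None, *, degree: int = 1) -> FPFit:
    """Exhaustive search for the best-fitting FP of the given degree.

    All 8 FP1 models or all 36 FP2 models (power pairs with repetition) are
    fitted; the smallest deviance wins, ties broken toward the earlier
    (simpler) candidate in enumeration order.
    """
    best: FPFit | None = None
    for powers in fp_power_sets(degree):
        fit = fit_fp_fixed(y, x, covariates, powers)
        if best is None or fit.deviance < best.deviance:
            best = fit
    assert best is not None
    return best


def compare_fp(fit_small: FPFit, fit_big: FPFit) -> LRTestResult:
    """Likelihood-ratio comparison of a simpler against a richer FP fit.

    Degrees of freedom follow the usual FP convention: FP1 vs linear 1,
    FP2 vs FP1 2, FP2 vs linear 3.  Negative statistics (the richer family
    contains the simpler one, so they arise only from roundoff) are clamped
    to zero.
    """
    if fit_small.n != fit_big.n:
        raise IncomparableFitsError(
            f"fits use different data: n={fit_small.n} vs n={fit_big.n}"
        )
    rank_s = _FAMILY_RANK[fit_small.family.removeprefix("meta_")]
    rank_b = _FAMILY_RANK[fit_big.family.removeprefix("meta_")]
    df = _LR_DF.get((rank_s, rank_b), 1)
    statistic = fit_small.deviance - fit_big.deviance
    if statistic < 0:
        statistic = 0.0
    p = float(stats.chi2.sf(statistic, df))
    return LRTestResult(statistic=float(statistic), df=df, p=p)


@dataclass
class CausalCurve:
    """An exposure-response difference curve anchored at a reference point.

    ``difference[i]`` is the modelled outcome difference (kg) between exposure
    ``grid[i]`` and ``reference`` (nmol/L); 95% pointwise confidence bounds
    come from the covariance of the FP coefficients via the linear contrast
    b(x) - b(reference).  The curve is exactly 0 with zero-width interval at
    the reference.
    """

    grid: np.ndarray
    difference: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    reference: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.grid,
                "difference": self.difference,
                "lower95": self.lower95,
                "upper95": self.upper95,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def at(self, x: float) -> tuple[float, float, float]:
        """(difference, lower95, upper95) at the grid point closest to x."""
        i = int(np.argmin(np.abs(self.grid - x)))
        return float(self.difference[i]), float(self.lower95[i]), float(self.upper95[i])


def _curve_from_contrast(
    basis_fn,
    fit: FPFit,
    reference: float,
    grid,
) -> CausalCurve:
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if np.any(grid <= 0) or reference <= 0:
        raise DomainError("curve grid and reference must be strictly positive")
    if fit.x_range is not None:
        lo, hi = fit.x_range
        if reference < lo or reference > hi:
            warnings.warn(
                f"reference {reference} lies outside the observed exposure "
                f"range [{lo:.1f}, {hi:.1f}]",
                stacklevel=3,
            )
    contrast = basis_fn(grid, fit.powers) - basis_fn(
        np.full_like(grid, reference), fit.powers
    )
    beta = fit.fp_coefficients
    cov = fit.fp_covariance
    diff = contrast @ beta
    var = np.einsum("ij,jk,ik->i", contrast, cov, contrast)
    se = np.sqrt(np.clip(var, 0.0, None))
    z = stats.norm.ppf(0.975)
    return CausalCurve(
        grid=grid,
        difference=diff,
        lower95=diff - z * se,
        upper95=diff + z * se,
        reference=float(reference),
    )


def curve_from_fp(fit: FPFit, reference: float = 50.0, grid=None) -> CausalCurve:
    """Reference-anchored difference curve from a directly fitted FP model.

    Covariates are held fixed: only the FP block of coefficients enters the
    contrast, so the curve is the adjusted mean outcome difference between
    each grid exposure and the reference.
    """
    if grid is None:
        grid = np.arange(15.0, 90.0 + 1.0, 1.0)
    return _curve_from_contrast(fp_basis, fit, reference, grid)
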