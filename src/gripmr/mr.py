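"""Weighted allele score, instrument diagnostics and linear Mendelian
randomization.

The instrument is a single weighted genetic score: the weighted average of
exposure-increasing allele counts, with GWAS effect sizes (on ln 25(OH)D) as
weights.  Linear MR is the Wald ratio of the covariate-adjusted
score-outcome and score-exposure coefficients — identical to two-stage least
squares with a single instrument — reported per 25 nmol/L of genetically
proxied 25(OH)D.  Diagnostics cover instrument strength (incremental R^2 and
the first-stage F statistic) and a scan for instrument-confounder
association, the standard empirical check for horizontal pleiotropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import mr_design, subset_sex
from .exceptions import (
    DegenerateInstrumentError,
    InstrumentMismatchError,
    WeakDenominatorError,
)
from .fracpoly import _as_matrix, _ols
from .instruments import InstrumentSpec, orient_instrument

__all__ = [
    "FirstStageResult",
    "MRResult",
    "weighted_score",
    "first_stage",
    "linear_mr",
    "confounder_scan",
    "run_linear_mr",
]


def weighted_score(
    genotypes: pd.DataFrame, instrument: Sequence[InstrumentSpec]
) -> pd.Series:
    """Weighted average of exposure-increasing allele dosages.

    Z_i = sum_j w_j g_ij / sum_j w_j after orienting every SNP so its weight
    is positive.  Being an average, the score is invariant to rescaling all
    weights by a common factor.
    """
    missing = [s.snp_id for s in instrument if s.snp_id not in genotypes.columns]
    if missing:
        raise InstrumentMismatchError(
            f"genotype table lacks instrument SNPs: {missing}"
        )
    oriented, g = orient_instrument(instrument, genotypes)
    w = np.array([s.weight for s in oriented])
    mat = g[[s.snp_id for s in oriented]].to_numpy(dtype=float)
    z = mat @ w / w.sum()
    return pd.Series(z, index=genotypes.index, name="score")


def _design_with_z(z: np.ndarray, covariates) -> tuple[np.ndarray, int]:
    cmat, _ = _as_matrix(covariates)
    n = z.shape[0]
    blocks = [np.ones((n, 1)), z[:, None]]
    if cmat is not None:
        blocks.append(cmat)
    return np.hstack(blocks), 1  # index of the z column


@dataclass
class FirstStageResult:
    """Instrument-exposure regression summary."""

    beta_zx: float
    se: float
    r2_partial: float  # incremental R^2 of the score beyond covariates
    f_statistic: float  # squared t of the score term (partial F, 1 df)
    n: int


def first_stage(Z, X, covariates=None) -> FirstStageResult:
    """OLS of exposure on the score plus covariates, with strength metrics.

    ``r2_partial`` is the increase in R^2 from adding the score to the
    covariate-only model; ``f_statistic`` is the squared t statistic of the
    score term (the partial F with one numerator df).
    """
    z = np.asarray(Z, dtype=float)
    x = np.asarray(X, dtype=float)
    if z.std() == 0:
        raise DegenerateInstrumentError("allele score is constant")
    design, zi = _design_with_z(z, covariates)
    beta, cov, rss_full, _ = _ols(design, x)
    reduced = np.delete(design, zi, axis=1)
    _, _, rss_red, _ = _ols(reduced, x)
    tss = float(((x - x.mean()) ** 2).sum())
    r2_partial = (rss_red - rss_full) / tss if tss > 0 else 0.0
    se = float(np.sqrt(cov[zi, zi]))
    f = (beta[zi] / se) ** 2 if se > 0 else np.inf
    return FirstStageResult(
        beta_zx=float(beta[zi]),
        se=se,
        r2_partial=float(r2_partial),
        f_statistic=float(f),
        n=int(x.shape[0]),
    )


@dataclass
class MRResult:
    """A linear MR estimate, reported per 25 nmol/L of 25(OH)D."""

    beta_per_25: float
    se: float
    ci95: tuple[float, float]
    first_stage_r2: float
    f_statistic: float
    beta_zx: float
    beta_zy: float
    n: int

    @property
    def beta_per_nmol(self) -> float:
        return self.beta_per_25 / 25.0


def linear_mr(Z, X, Y, covariates=None) -> MRResult:
    """Wald-ratio MR with a single weighted-score instrument.

    beta = beta_zy / beta_zx from covariate-adjusted regressions of outcome
    and exposure on the score; the delta-method SE treats the denominator as
    fixed (se_zy / |beta_zx|), which is accurate in the very strong
    instrument regime this method targets — a warning is emitted when the
    first-stage F falls below 10.  Invariant to affine rescaling of Z.
    """
    z = np.asarray(Z, dtype=float)
    x = np.asarray(X, dtype=float)
    y = np.asarray(Y, dtype=float)
    fs = first_stage(z, x, covariates)
    if abs(fs.beta_zx) < 1e-12 * max(1.0, np.std(x) / max(np.std(z), 1e-300)):
        raise WeakDenominatorError(
            f"instrument-exposure coefficient {fs.beta_zx:.3e} is numerically zero"
        )
    if fs.f_statistic < 10:
        warnings.warn(
            f"first-stage F = {fs.f_statistic:.1f} < 10: the fixed-denominator "
            "delta-method SE is unreliable in this weak-instrument regime",
            stacklevel=2,
        )
    design, zi = _design_with_z(z, covariates)
    beta_y, cov_y, _, _ = _ols(design, y)
    beta_zy = float(beta_y[zi])
    se_zy = float(np.sqrt(cov_y[zi, zi]))
    beta = beta_zy / fs.beta_zx
    se = abs(se_zy / fs.beta_zx)
    z975 = stats.norm.ppf(0.975)
    beta25, se25 = 25.0 * beta, 25.0 * se
    return MRResult(
        beta_per_25=beta25,
        se=se25,
        ci95=(beta25 - z975 * se25, beta25 + z975 * se25),
        first_stage_r2=fs.r2_partial,
        f_statistic=fs.f_statistic,
        beta_zx=fs.beta_zx,
        beta_zy=beta_zy,
        n=fs.n,
    )


def confounder_scan(Z, confounders: pd.DataFrame) -> pd.DataFrame:
    """Association of the score with each potential confounder.

    Numeric confounders are regressed on the score (slope, SE, p); for
    categorical confounders a global F test of score differences across
    levels is reported.  P-values are raw — no multiplicity adjustment.
    Degenerate (constant) columns are flagged and excluded from testing.
    """
    z = np.asarray(Z, dtype=float)
    rows = []
    for name in confounders.columns:
        col = confounders[name]
        if col.nunique(dropna=False) < 2:
            rows.append((name, "degenerate", np.nan, np.nan, np.nan, "constant column"))
            continue
        if pd.api.types.is_numeric_dtype(col):
            design = np.column_stack([np.ones_like(z), z])
            beta, cov, _, _ = _ols(design, col.to_numpy(dtype=float))
            se = float(np.sqrt(cov[1, 1]))
            t = beta[1] / se
            p = 2.0 * stats.t.sf(abs(t), df=len(z) - 2)
            rows.append((name, "numeric", float(beta[1]), se, float(p), ""))
        else:
            groups = [z[(col == lev).to_numpy()] for lev in col.unique()]
            groups = [g for g in groups if len(g) > 0]
            f, p = stats.f_oneway(*groups)
            rows.append((name, "categorical", float(f), np.nan, float(p), "global F test"))
    return pd.DataFrame(
        rows, columns=["confounder", "type", "statistic", "se", "p", "note"]
    )


def run_linear_mr(
    cohort: pd.DataFrame,
    instrument: Sequence[InstrumentSpec] | None = None,
    sex: str | None = None,
    n_pcs: int = 10,
) -> MRResult:
    """Convenience pipeline: score (reusing a precomputed ``score`` column if
    present), standard genetic-arm covariates, linear MR."""
    sub = subset_sex(cohort, sex) if sex is not None else cohort.reset_index(drop=True)
    if "score" in sub.columns:
        z = sub["score"]
    else:
        if instrument is None:
            raise InstrumentMismatchError(
                "cohort has no 'score' column and no instrument was given"
            )
        z = weighted_score(sub, instrument)
    covs = mr_design(sub, n_pcs=n_pcs)
    return linear_mr(z, sub["exposure"], sub["outcome"], covs)
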