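"""Synthetic UK-Biobank-like cohorts for the 25(OH)D / grip-strength analysis.

The generator produces participant tables with the statistical structure the
downstream methods assume: a weighted allele score that explains a calibrated
share of exposure variance, a log-normal 25(OH)D distribution with seasonal
and supplementation structure truncated at the 10 nmol/L assay floor, shared
confounding of exposure and outcome (BMI, age, smoking, deprivation), and a
configurable true causal function linking 25(OH)D to grip strength.  All
moments are calibrated against large-cohort summary statistics (exposure
~50 (21) nmol/L; grip 41.9 (8.9) kg in males, 25.2 (6.3) kg in females).

Design notes
------------
* The exposure is built on the natural-log scale (GWAS weights live there)
  and exponentiated, which keeps X > 0 and makes the score multiplicative.
* The log-linear predictor is standardised empirically and mapped onto the
  log-normal (mu, sigma) implied by the target mean/SD, so realised exposure
  moments match the targets closely at large n; the score coefficient is then
  solved numerically (Brent root find on the realised R^2) so the score's
  variance-explained for X hits ``target_score_r2``.
* Sex-specific outcome intercepts and noise SDs are solved from the realised
  variance of the structural part, so outcome moments also match the targets.
* Seasonality is a sinusoid peaking in July; amplitude in nmol/L, converted
  to the log scale by dividing by the target mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, InvalidInstrumentError
from .instruments import InstrumentSpec, default_instrument, validate_instrument

__all__ = [
    "CausalFunction",
    "NullEffect",
    "LinearEffect",
    "PlateauEffect",
    "FPEffect",
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "load_config",
    "default_config",
    "causal_fn_from_dict",
]

ASSAY_FLOOR = 10.0  # nmol/L, lower bound of the validated assay range
OUTCOME_FLOOR = 0.1  # kg; recorded grip strength is strictly positive

SMOKING_LEVELS = ("never", "previous", "current")


# ---------------------------------------------------------------------------
# True causal functions
# ---------------------------------------------------------------------------


class CausalFunction:
    """Mean effect of exposure X (nmol/L) on outcome Y (kg).

    Subclasses implement ``__call__``; ``true_difference`` gives the exact
    outcome difference between two exposure values, used as ground truth in
    curve-recovery tests.
    """

    kind = "base"

    def __call__(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def true_difference(self, x, reference: float = 50.0):
        return self(np.asarray(x, dtype=float)) - self(np.asarray(reference, dtype=float))

    def to_dict(self) -> dict:
        return {"kind": self.kind}


@dataclass(frozen=True)
class NullEffect(CausalFunction):
    """No causal effect of 25(OH)D on grip strength."""

    kind = "null"

    def __call__(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class LinearEffect(CausalFunction):
    """Constant slope in kg per nmol/L."""

    slope: float = 0.01
    kind = "linear"

    def __call__(self, x):
        return self.slope * np.asarray(x, dtype=float)

    def to_dict(self):
        return {"kind": "linear", "slope": self.slope}


@dataclass(frozen=True)
class PlateauEffect(CausalFunction):
    """Linear gain below a knot, flat above it (threshold dose-response)."""

    slope: float = 0.04
    knot: float = 50.0
    kind = "plateau"

    def __call__(self, x):
        return self.slope * np.minimum(np.asarray(x, dtype=float), self.knot)

    def to_dict(self):
        return {"kind": "plateau", "slope": self.slope, "knot": self.knot}


@dataclass(frozen=True)
class FPEffect(CausalFunction):
    """A single fractional-polynomial shape, coefficient * x**power
    (power 0 means ln x)."""

    power: float = 0.0
    coefficient: float = 1.0
    kind = "fp"

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        base = np.log(x) if self.power == 0.0 else x**self.power
        return self.coefficient * base

    def to_dict(self):
        return {"kind": "fp", "power": self.power, "coefficient": self.coefficient}


_CAUSAL_KINDS = {
    "null": NullEffect,
    "linear": LinearEffect,
    "plateau": PlateauEffect,
    "fp": FPEffect,
}


def causal_fn_from_dict(spec: Mapping) -> CausalFunction:
    """Build a causal function from a config mapping like
    ``{"kind": "plateau", "slope": 0.04, "knot": 50}``."""
    spec = dict(spec)
    kind = spec.pop("kind")
    try:
        cls = _CAUSAL_KINDS[kind]
    except KeyError:
        raise ConfigurationError(
            f"unknown causal function kind {kind!r}; choose from {sorted(_CAUSAL_KINDS)}"
        ) from None
    return cls(**spec)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _default_confounder_effects() -> dict[str, tuple[float, float]]:
    # (effect on log-exposure predictor per SD of confounder,
    #  effect on outcome in kg per SD of confounder)
    return {
        "bmi": (-0.20, 1.0),
        "age": (-0.10, -2.5),
        "smoking": (-0.15, -0.8),  # current-smoker indicator, standardised
        "townsend": (-0.10, -0.3),
    }


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator.

    Defaults reproduce the large-cohort summary statistics the analysis is
    calibrated against; the causal function defaults to a linear effect of
    0.01 kg per nmol/L (0.25 kg per 25 nmol/L).
    """

    n: int = 20_000
    seed: int = 0
    sex_fraction_male: float = 0.467
    causal_fn: CausalFunction = field(default_factory=LinearEffect)
    target_score_r2: float = 0.025
    exposure_mean: float = 49.9
    exposure_sd: float = 21.1
    outcome_mean_male: float = 41.9
    outcome_sd_male: float = 8.9
    outcome_mean_female: float = 25.2
    outcome_sd_female: float = 6.3
    confounder_effects: dict[str, tuple[float, float]] = field(
        default_factory=_default_confounder_effects
    )
    season_amplitude: float = 8.0  # nmol/L, peak-to-mean seasonal swing
    supplement_prevalence: float = 0.065
    supplement_effect: float = 10.0  # nmol/L shift among supplement users
    age_range: tuple[int, int] = (37, 73)
    smoking_probs: tuple[float, float, float] = (0.55, 0.35, 0.10)
    bmi_mean: float = 27.4
    bmi_sd: float = 4.7
    townsend_mean: float = -1.55
    townsend_sd: float = 2.9
    n_pcs: int = 10
    #: optional per-age-band multipliers of the causal effect (<50, 50-59,
    #: 60-64, 65+); None means the effect is age-constant.
    age_band_effect_scale: tuple[float, float, float, float] | None = None
    #: direct effect of the (standardised) allele score on BMI — a planted
    #: pleiotropic path, used to exercise the confounder scan.  0 = none.
    bmi_score_leak: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if self.exposure_sd <= 0:
            raise ConfigurationError("exposure_sd must be positive")
        if not (0.0 <= self.target_score_r2 < 1.0):
            raise ConfigurationError("target_score_r2 must lie in [0, 1)")
        if not (0.0 <= self.supplement_prevalence <= 1.0):
            raise ConfigurationError("supplement_prevalence must lie in [0, 1]")
        if not (0.0 <= self.sex_fraction_male <= 1.0):
            raise ConfigurationError("sex_fraction_male must lie in [0, 1]")
        if isinstance(self.causal_fn, Mapping):
            self.causal_fn = causal_fn_from_dict(self.causal_fn)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "confounder_effects" in raw:
        raw["confounder_effects"] = {
            k: tuple(v) for k, v in raw["confounder_effects"].items()
        }
    for key in ("age_range", "smoking_probs", "age_band_effect_scale"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)


def default_config(**overrides) -> SimulationConfig:
    """The packaged 'ukb_like' configuration, optionally overridden."""
    import importlib.resources

    ref = importlib.resources.files("gripmr.data") / "ukb_like.yaml"
    with importlib.resources.as_file(ref) as path:
        cfg = load_config(path)
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n: int,
    instrument: Sequence[InstrumentSpec],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Independent Binomial(2, allele_freq) dosages per SNP.

    SNPs are drawn in linkage equilibrium, mirroring an LD-clumped
    instrument.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    validate_instrument(instrument)
    for snp in instrument:
        if not (0.0 < snp.allele_freq < 1.0):  # defensive: specs built outside the constructor
            raise InvalidInstrumentError(f"{snp.snp_id}: allele_freq outside (0,1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = {
        snp.snp_id: rng.binomial(2, snp.allele_freq, size=n).astype(float)
        for snp in instrument
    }
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def _standardise(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def simulate_cohort(
    config: SimulationConfig,
    instrument: Sequence[InstrumentSpec] | None = None,
) -> pd.DataFrame:
    """Generate a complete synthetic cohort table.

    Columns: id, sex, age, month, supplement, smoking, bmi, townsend,
    pc1..pc10, one dosage column per instrument SNP, score, exposure
    (25(OH)D, nmol/L) and outcome (grip strength, kg).  Identical
    (config, instrument) inputs give bit-identical tables.
    """
    from scipy.optimize import brentq

    from .mr import weighted_score

    if instrument is None:
        instrument = default_instrument()
    validate_instrument(instrument)
    cfg = config
    n = cfg.n
    rng = np.random.default_rng(cfg.seed)

    # --- covariates (fixed draw order for determinism) ---
    male = rng.random(n) < cfg.sex_fraction_male
    age = rng.integers(cfg.age_range[0], cfg.age_range[1] + 1, size=n)
    month = rng.integers(1, 13, size=n)
    supplement = (rng.random(n) < cfg.supplement_prevalence).astype(int)
    smoking = rng.choice(SMOKING_LEVELS, size=n, p=cfg.smoking_probs)
    genotypes = simulate_genotypes(n, instrument, rng)
    score = weighted_score(genotypes, instrument).to_numpy()
    score_std = _standardise(score)
    bmi = rng.normal(cfg.bmi_mean, cfg.bmi_sd, size=n) + cfg.bmi_score_leak * score_std
    townsend = rng.normal(cfg.townsend_mean, cfg.townsend_sd, size=n)
    pcs = rng.standard_normal((n, cfg.n_pcs))
    exposure_noise = rng.standard_normal(n)
    outcome_noise = rng.standard_normal(n)

    conf_std = {
        "bmi": _standardise(bmi),
        "age": _standardise(age.astype(float)),
        "smoking": _standardise((smoking == "current").astype(float)),
        "townsend": _standardise(townsend),
    }
    unknown = set(cfg.confounder_effects) - set(conf_std)
    if unknown:
        raise ConfigurationError(f"unknown confounders in config: {sorted(unknown)}")

    # --- exposure on the log scale ---
    season = np.cos(2.0 * np.pi * (month - 7) / 12.0)
    fixed_log = (
        (cfg.season_amplitude / cfg.exposure_mean) * season
        + (cfg.supplement_effect / cfg.exposure_mean) * supplement
        + sum(bx * conf_std[c] for c, (bx, _) in cfg.confounder_effects.items())
        + exposure_noise
    )
    cv2 = (cfg.exposure_sd / cfg.exposure_mean) ** 2
    sigma_star = math.sqrt(math.log1p(cv2))
    mu_star = math.log(cfg.exposure_mean) - 0.5 * sigma_star**2

    def make_exposure(a: float) -> np.ndarray:
        raw = a * score_std + fixed_log
        raw = _standardise(raw)
        return np.maximum(np.exp(mu_star + sigma_star * raw), ASSAY_FLOOR)

    def r2_gap(a: float) -> float:
        x = make_exposure(a)
        r = np.corrcoef(score_std, x)[0, 1]
        return r * r - cfg.target_score_r2

    if cfg.target_score_r2 == 0.0 or score_std.std() == 0.0 or r2_gap(0.0) >= 0.0:
        a_score = 0.0
    else:
        hi = 0.5
        while r2_gap(hi) < 0.0:
            hi *= 2.0
            if hi > 64.0:
                raise ConfigurationError(
                    f"target_score_r2={cfg.target_score_r2} unattainable with the "
                    "configured noise structure"
                )
        a_score = brentq(r2_gap, 0.0, hi, xtol=1e-6)
    exposure = make_exposure(a_score)

    # --- outcome ---
    effect = np.asarray(cfg.causal_fn(exposure), dtype=float)
    if cfg.age_band_effect_scale is not None:
        from .observational import assign_age_band

        band = assign_age_band(age)
        effect = effect * np.asarray(cfg.age_band_effect_scale, dtype=float)[band - 1]
    structural = effect + sum(
        by * conf_std[c] for c, (_, by) in cfg.confounder_effects.items()
    )
    outcome = np.empty(n)
    targets = {
        True: (cfg.outcome_mean_male, cfg.outcome_sd_male),
        False: (cfg.outcome_mean_female, cfg.outcome_sd_female),
    }
    for is_male, (mean_t, sd_t) in targets.items():
        mask = male == is_male
        if not mask.any():
            continue
        var_struct = structural[mask].var() if mask.sum() > 1 else 0.0
        if var_struct >= sd_t**2:
            raise ConfigurationError(
                f"structural outcome variance {var_struct:.2f} exceeds the "
                f"target SD^2 {sd_t**2:.2f} for {'males' if is_male else 'females'}"
            )
        sd_noise = math.sqrt(sd_t**2 - var_struct)
        outcome[mask] = (
            mean_t
            - structural[mask].mean()
            + structural[mask]
            + sd_noise * outcome_noise[mask]
        )
    outcome = np.maximum(outcome, OUTCOME_FLOOR)

    cohort = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sex": np.where(male, "male", "female"),
            "age": age,
            "month": month,
            "supplement": supplement,
            "smoking": smoking,
            "bmi": bmi,
            "townsend": townsend,
        }
    )
    for j in range(cfg.n_pcs):
        cohort[f"pc{j + 1}"] = pcs[:, j]
    for snp in instrument:
        cohort[snp.snp_id] = genotypes[snp.snp_id].to_numpy()
    cohort["score"] = score
    cohort["exposure"] = exposure
    cohort["outcome"] = outcome
    return cohort


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort as tab-delimited text, one row per participant."""
    cohort.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited cohort table written by :func:`write_cohort`."""
    return pd.read_csv(path, sep="\t")
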