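"""Genetic instrument definitions for 25(OH)D.

An instrument is a list of independent SNPs, each with a per-allele weight on
the natural-log 25(OH)D scale (as reported by a discovery GWAS) and an effect
allele frequency.  The default 6-SNP instrument shipped with the package is a
synthetic stand-in with weights and frequencies on the scale of published
vitamin-D GWAS hits; the simulator recalibrates the score-exposure coupling
to a target variance-explained, so only the relative weights matter.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInstrumentError

__all__ = [
    "InstrumentSpec",
    "load_instrument",
    "write_instrument",
    "default_instrument",
    "orient_instrument",
    "validate_instrument",
]

_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class InstrumentSpec:
    """One SNP of a weighted allele-score instrument.

    Parameters
    ----------
    snp_id : str
        rsID or any unique label; must match a genotype dosage column.
    effect_allele : str
        Single character A/C/G/T; the allele the weight refers to.
    weight : float
        Per-allele effect on ln 25(OH)D from the discovery GWAS.  Nonzero and
        finite; negative weights are permitted on input and flipped at
        orientation time.
    allele_freq : float
        Effect-allele frequency, strictly inside (0, 1).
    """

    snp_id: str
    effect_allele: str
    weight: float
    allele_freq: float

    def __post_init__(self) -> None:
        if self.effect_allele not in _ALLELES:
            raise InvalidInstrumentError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} is not one of A/C/G/T"
            )
        if not np.isfinite(self.weight) or self.weight == 0.0:
            raise InvalidInstrumentError(
                f"{self.snp_id}: weight must be finite and nonzero, got {self.weight!r}"
            )
        if not (0.0 < self.allele_freq < 1.0):
            raise InvalidInstrumentError(
                f"{self.snp_id}: allele frequency must lie strictly in (0, 1), "
                f"got {self.allele_freq!r}"
            )


def validate_instrument(instrument: Sequence[InstrumentSpec]) -> None:
    """Check list-level invariants (non-empty, unique SNP ids)."""
    if len(instrument) == 0:
        raise InvalidInstrumentError("instrument is empty")
    ids = [s.snp_id for s in instrument]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InvalidInstrumentError(f"duplicate SNP ids in instrument: {dupes}")


def orient_instrument(
    instrument: Sequence[InstrumentSpec],
    genotypes: pd.DataFrame | None = None,
) -> tuple[list[InstrumentSpec], pd.DataFrame | None]:
    """Orient every SNP to its exposure-increasing allele.

    A negative weight means the listed effect allele lowers 25(OH)D: the
    dosage is flipped (g -> 2 - g), the frequency complemented, and the weight
    negated, so all oriented weights are positive.
    """
    from .exceptions import OrientationError

    validate_instrument(instrument)
    oriented: list[InstrumentSpec] = []
    g = genotypes.copy() if genotypes is not None else None
    for snp in instrument:
        if snp.weight < 0:
            snp = replace(snp, weight=-snp.weight, allele_freq=1.0 - snp.allele_freq)
            if g is not None and snp.snp_id in g.columns:
                g[snp.snp_id] = 2.0 - g[snp.snp_id]
        if snp.weight <= 0:
            raise OrientationError(f"{snp.snp_id}: non-positive weight after orientation")
        oriented.append(snp)
    return oriented, g


def load_instrument(path: str | Path) -> list[InstrumentSpec]:
    """Read a 4-column TSV (snp_id, effect_allele, weight, allele_freq)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"snp_id", "effect_allele", "weight", "allele_freq"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInstrumentError(f"instrument file missing columns: {sorted(missing)}")
    instrument = [
        InstrumentSpec(str(r.snp_id), str(r.effect_allele), float(r.weight), float(r.allele_freq))
        for r in df.itertuples(index=False)
    ]
    validate_instrument(instrument)
    return instrument


def write_instrument(instrument: Iterable[InstrumentSpec], path: str | Path) -> None:
    """Write the instrument as a 4-column TSV."""
    df = pd.DataFrame(
        [(s.snp_id, s.effect_allele, s.weight, s.allele_freq) for s in instrument],
        columns=["snp_id", "effect_allele", "weight", "allele_freq"],
    )
    df.to_csv(path, sep="\t", index=False)


def default_instrument() -> list[InstrumentSpec]:
    """The packaged synthetic 6-SNP instrument.

    Six independent variants on the scale of published 25(OH)D GWAS effects
    (ln-scale weights ~0.02-0.09); together, once the simulator calibrates the
    coupling, they explain ~2.5% of exposure variance.
    """
    ref = importlib.resources.files("gripmr.data") / "instrument_6snp_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_instrument(path)
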