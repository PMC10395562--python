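"""Exception hierarchy for gripmr.

Everything raised on purpose derives from :class:`GripMRError` so callers can
catch the package's own failures separately from programming errors.
"""


class GripMRError(Exception):
    """Base class for all gripmr errors."""


class ConfigurationError(GripMRError, ValueError):
    """A simulation or analysis configuration is internally inconsistent
    or unattainable (e.g. a variance target smaller than structural variance)."""


class DomainError(GripMRError, ValueError):
    """Input values outside the mathematical domain of an operation
    (fractional-polynomial bases require strictly positive exposures)."""


class InvalidInstrumentError(GripMRError, ValueError):
    """An instrument definition violates its invariants (allele frequency
    outside (0,1), zero/non-finite weight, duplicate SNP id)."""


class InstrumentMismatchError(GripMRError, KeyError):
    """Instrument SNPs not present as genotype columns."""


class OrientationError(GripMRError, ValueError):
    """A weight remains non-positive after orienting to exposure-increasing
    alleles; the instrument file is malformed."""


class DegenerateInstrumentError(GripMRError, ValueError):
    """The allele score is constant; no first-stage model can be fitted."""


class WeakDenominatorError(GripMRError, ZeroDivisionError):
    """The instrument-exposure coefficient is numerically zero; the Wald
    ratio is undefined."""


class InfeasibleStratificationError(GripMRError, ValueError):
    """Fewer participants than requested strata."""


class SmallStratumError(GripMRError, ValueError):
    """A stratum is too small to support the covariate-adjusted regression;
    reduce the number of strata."""


class InsufficientDataError(GripMRError, ValueError):
    """Too few rows for a stable analysis (below the configured floor)."""


class IncomparableFitsError(GripMRError, ValueError):
    """Likelihood-ratio comparison requested between fits on different data."""


class SingularFitError(GripMRError, ValueError):
    """Rank-deficient design matrix; the regression has no unique solution."""
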