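"""Exception types raised across the package.

All domain errors subclass :class:`ValueError` so callers that do not care
about the distinction can catch one base class.
"""


class CustressError(ValueError):
    """Base class for all domain errors raised by custress."""


class InvalidParameterError(CustressError):
    """A schedule or simulator parameter is outside its valid range."""


class IncompatibleScheduleError(CustressError):
    """Two schedules cannot be compared (e.g. different lengths)."""


class InsufficientReplicationError(CustressError):
    """A statistical routine received fewer replicates than it requires."""


class SimulationDivergedError(CustressError):
    """Numerical integration produced a non-finite trajectory."""


class UndefinedStatisticError(CustressError):
    """The requested statistic is undefined for the given input
    (constant traits, zero variance, singular covariance...)."""


class ConfigurationError(CustressError):
    """Inconsistent analysis configuration (e.g. mismatched alpha levels)."""


class TableValidationError(CustressError):
    """A replicate table failed structural validation."""
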