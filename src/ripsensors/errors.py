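"""Exception hierarchy for the ripsensors package.

Every error raised on a user-facing code path derives from
:class:`RipSensorsError`, so callers can catch one base class.
"""


class RipSensorsError(Exception):
    """Base class for all ripsensors errors."""


class FormatError(RipSensorsError):
    """A file could not be parsed as the expected on-disk format."""


class EmptyRecordingError(RipSensorsError):
    """No channel of a recording could be mapped or read."""


class ValidationError(RipSensorsError, ValueError):
    """An input value violates a documented precondition."""


class ParseError(RipSensorsError):
    """A delimited text file contains a row that cannot be interpreted."""


class ConfigurationError(RipSensorsError):
    """A required channel, column or setting is missing or inconsistent."""


class ScheduleError(RipSensorsError):
    """A synthetic event/artifact schedule is contradictory or out of range."""


class PesCorruptError(RipSensorsError):
    """An esophageal pressure signal has no usable samples left to clean."""


class EmptyBandError(RipSensorsError):
    """A frequency band contains no spectrum bins at the given resolution."""


class UndefinedStatisticError(RipSensorsError):
    """A statistic (skewness, Pearson r) is undefined on a constant input."""


class UnderdeterminedFitError(RipSensorsError):
    """Fewer observations than coefficients; the least-squares fit is underdetermined."""


class CollinearityError(RipSensorsError):
    """The design matrix is rank deficient."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class CorruptModelError(RipSensorsError):
    """A serialized model file is internally inconsistent."""


class InsufficientDataError(RipSensorsError):
    """Too few rows for the requested cross-validation layout."""


class EmptyCohortError(RipSensorsError):
    """No recording in the cohort passed the inclusion criteria."""


class ConventionMismatchError(RipSensorsError):
    """A model's stored feature conventions differ from the extraction settings."""

    def __init__(self, message: str, convention: str = ""):
        super().__init__(message)
        self.convention = convention
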