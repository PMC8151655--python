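"""Exception hierarchy.

Every error raised by the package derives from :class:`EnzymixError`, so
callers can catch a single base class at pipeline boundaries.
"""


class EnzymixError(Exception):
    """Base class for all package errors."""


class InputError(EnzymixError, ValueError):
    """Invalid argument values (negative concentrations, bad fractions...)."""


class SchemaError(EnzymixError):
    """A CSV is missing required columns."""


class ParseError(EnzymixError):
    """A CSV row could not be parsed; the message names the row."""


class InsufficientDataError(InputError):
    """Too few points/doses/replicates for the requested computation."""


class FitError(EnzymixError):
    """A model fit failed or is invalid; may carry the best attempt."""

    def __init__(self, message, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


class ClassificationError(EnzymixError):
    """Mechanism classification could not be performed."""


class UnitConversionError(EnzymixError):
    """Activity-unit conversion applied to the wrong measurement type."""


class DataQualityError(EnzymixError):
    """Data fail quality requirements (e.g. effect fractions out of range)."""


class BootstrapError(EnzymixError):
    """Bootstrap resampling is not possible with the given replication."""
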