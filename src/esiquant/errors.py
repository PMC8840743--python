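"""Exception hierarchy.

All package-specific failures derive from :class:`EsiQuantError` so callers
can catch one base class; subclasses distinguish bad file formats, violated
preconditions, and degenerate numerical situations.
"""


class EsiQuantError(Exception):
    """Base class for all esiquant errors."""


class FormatError(EsiQuantError):
    """A delimited-text file does not match the expected schema."""


class ValidationError(EsiQuantError):
    """A value violates a domain invariant (pH, mode, config field, ...)."""


class InsufficientDataError(EsiQuantError):
    """Too few data points to perform an operation (e.g. < 3 calibration points)."""


class DegenerateCalibrationError(EsiQuantError):
    """Calibration fit produced a non-positive response factor."""


class UndefinedRetentionTimeError(EsiQuantError):
    """No detected record from which to compute a retention time."""


class UndefinedRatioError(EsiQuantError):
    """Positive/negative area ratio requested where neither mode was detected."""


class UnavailableConditionError(EsiQuantError):
    """No trained model (or no training data) for the requested condition."""
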