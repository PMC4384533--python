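"""Exception hierarchy.

Every error raised by this package derives from :class:`BombpulseError`, and
also from :class:`ValueError` so that callers using generic validation
handling keep working.
"""


class BombpulseError(Exception):
    """Base class for all errors raised by bombpulse."""


class ParseError(BombpulseError, ValueError):
    """A delimited-text input could not be parsed (names the offending row)."""


class DomainError(BombpulseError, ValueError):
    """A date or value falls outside the domain of a calibration curve."""


class SpliceError(BombpulseError, ValueError):
    """Joining two curve segments would violate the strictly-increasing-year invariant."""


class ParameterError(BombpulseError, ValueError):
    """An operation was called with an invalid tuning parameter."""


class ReductionError(BombpulseError, ValueError):
    """Raw AMS quantities cannot be reduced to a fraction-modern value."""


class CorrectionError(BombpulseError, ValueError):
    """A blank/background correction is impossible (e.g. blank mass dominates)."""


class CalibrationError(BombpulseError, ValueError):
    """Calibration of a measurement against a curve failed."""


class DegenerateLikelihoodError(CalibrationError):
    """Zero combined variance everywhere with no exact curve match."""


class FitError(BombpulseError, ValueError):
    """A model fit cannot be carried out on the given cohort."""


class RegressionError(BombpulseError, ValueError):
    """The predicted-vs-actual regression is not identifiable."""


class TracerError(BombpulseError, ValueError):
    """The stable-isotope tracer is degenerate (source delta equals base delta)."""
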