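"""Exception taxonomy for the MBW QC engine.

Error trials (empty or unreadable signal traces) are distinguished from
validation problems so the batch driver can classify a trial as *error*
and keep going, while genuine misuse of the API raises immediately.
"""


class MbwError(Exception):
    """Base class for all package errors."""


class FormatError(MbwError):
    """A trace or annotation file violates the documented layout."""


class ParseError(FormatError):
    """A cell could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class ErrorTrial(MbwError):
    """Empty or erroneous signal trace; the trial is classified *error*."""


class SchemaError(MbwError):
    """An annotation/rating record violates its schema."""


class ValidationError(MbwError):
    """A domain object violates one of its invariants."""


class SignalQualityError(MbwError):
    """A signal leaves its physical plausibility band."""


class CalibrationError(MbwError):
    """Two-point tracer calibration is ill-posed (equilibrated MM <= baseline)."""


class PhaseError(MbwError):
    """Washin/washout phase boundaries could not be identified."""


class UndefinedStatisticError(MbwError):
    """A per-breath statistic is undefined (e.g. zero median tidal volume)."""


class DegenerateWashoutError(MbwError):
    """Tracer concentration never decays; FRC is undefined."""
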