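"""Exception hierarchy for the ergspectra pipeline."""


class ErgSpectraError(Exception):
    """Base class for all package errors."""


class ValidationError(ErgSpectraError):
    """A domain object violates one of its invariants."""


class ParseError(ErgSpectraError):
    """A session or config file is malformed; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CalibrationError(ErgSpectraError):
    """The V-log(I) calibration is unusable (e.g. non-positive slope)."""


class FitError(ErgSpectraError):
    """Least-squares fitting failed."""


class DegenerateFitError(FitError):
    """The fit is ill-posed (no variance in the response)."""


class MissingAdaptationError(ErgSpectraError):
    """A required adaptation state is absent from the data."""
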