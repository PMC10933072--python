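"""Exception hierarchy for gaitmse.

All package errors derive from :class:`GaitError` so callers can catch one
base class; most also derive from the matching builtin (``ValueError`` etc.)
so generic handling keeps working.
"""


class GaitError(Exception):
    """Base class for all gaitmse errors."""


class InvalidParameterError(GaitError, ValueError):
    """A parameter violates its documented domain (e.g. non-positive stride)."""


class ConfigurationError(GaitError, ValueError):
    """A layout or run configuration is internally inconsistent."""


class MorphologyError(GaitError, ValueError):
    """A pressure trace does not show the expected stance morphology."""


class InsufficientEventsError(GaitError, ValueError):
    """Too few detected gait events to compute the requested quantity."""


class UndefinedNormalizationError(GaitError, ValueError):
    """Amplitude normalization is undefined (all-zero or non-positive trace)."""


class ToleranceError(GaitError, ValueError):
    """Entropy tolerance r is non-positive (e.g. constant input with r ~ SD)."""


class SeriesLengthError(GaitError, ValueError):
    """A time series is too short for the requested analysis."""


class InvalidScaleError(GaitError, ValueError):
    """Coarse-graining scale is out of range for the series."""


class RecordingParseError(GaitError, ValueError):
    """A recording file violates the documented CSV dialect."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class InputError(GaitError, ValueError):
    """Paired inputs are malformed (length mismatch, too few pairs)."""


class PipelineError(GaitError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
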