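"""Exception hierarchy for the microcirculation analysis pipeline.

All errors derive from :class:`MicrocircError` so callers can catch the
package's failures with one clause; most also derive from the closest
builtin (``ValueError`` / ``IOError``) so generic handling keeps working.
"""


class MicrocircError(Exception):
    """Base class for all package errors."""


class InputFormatError(MicrocircError, IOError):
    """The input container could not be read or decoded."""


class EmptyInputError(MicrocircError, ValueError):
    """A video or frame stack contained no frames."""


class ParameterError(MicrocircError, ValueError):
    """An argument is outside its valid domain."""


class ShapeError(MicrocircError, ValueError):
    """Array shapes are inconsistent."""


class DegenerateContentError(MicrocircError, ValueError):
    """Image content is too flat to support the requested operation
    (e.g. a constant frame offered for control-point selection)."""


class RemarkablenessError(MicrocircError, ValueError):
    """A matching window has no distinctive structure (zero variance);
    signals that control points must be re-seeded."""


class StabilizationError(MicrocircError, RuntimeError):
    """Motion estimation failed on some frame."""

    def __init__(self, frame_index: int, message: str | None = None):
        self.frame_index = frame_index
        super().__init__(message or f"stabilization failed at frame {frame_index}")


class NoBackgroundError(MicrocircError, ValueError):
    """A binary mask has no background pixel, so a distance transform
    is undefined."""


class DegenerateHistogramError(MicrocircError, ValueError):
    """Histogram-based threshold selection received constant input."""


class DegenerateTestError(MicrocircError, ValueError):
    """A statistical test is undefined (e.g. zero variance of paired
    differences)."""
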