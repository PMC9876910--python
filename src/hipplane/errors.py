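"""Exception hierarchy.

All geometric/physical input problems raise :class:`GeometryError` (a
``ValueError``), so callers can distinguish "your measurements are not
physically consistent" from programming errors.  Non-convergence of the
fixed-point solvers raises :class:`ConvergenceError` carrying the last
iterate so a caller can inspect how far the iteration got.
"""

from __future__ import annotations


class HipplaneError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(HipplaneError, ValueError):
    """Non-physical or inconsistent geometric input."""


class ValidationError(HipplaneError, ValueError):
    """Malformed input data (NaN/inf coordinates, bad schema fields)."""


class ConvergenceError(HipplaneError, RuntimeError):
    """A fixed-point iteration failed to converge within ``max_iter``.

    Attributes
    ----------
    last : object
        The last iterate (module-specific payload).
    """

    def __init__(self, message: str, last=None):
        super().__init__(message)
        self.last = last


class PipelineError(HipplaneError, RuntimeError):
    """Failure inside the bi-planar pipeline, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
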