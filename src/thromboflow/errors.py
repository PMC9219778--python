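"""Exception hierarchy for thromboflow.

Every error raised on a documented failure path derives from
:class:`ThromboflowError`, so callers (and the CLI) can distinguish bad input
(exit code 2) from solver non-convergence (exit code 3).
"""

from __future__ import annotations


class ThromboflowError(Exception):
    """Base class for all thromboflow errors."""


class InvalidInputError(ThromboflowError, ValueError):
    """A value violates a documented precondition (non-finite, negative, ...)."""


class GeometryError(InvalidInputError):
    """A grid does not have the topology an operation requires."""


class FormatError(ThromboflowError, ValueError):
    """A file could not be parsed; the message names the defect."""


class StabilityError(ThromboflowError):
    """A requested explicit time step violates the scheme's stability bound."""

    def __init__(self, message: str, dt: float, dt_max: float):
        super().__init__(message)
        self.dt = dt
        self.dt_max = dt_max


class ConvergenceError(ThromboflowError):
    """An iterative solve failed to meet its residual bound.

    Carries the residual history so the caller can diagnose or relax.
    """

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class DegenerateNormalizationError(InvalidInputError):
    """Max-min normalization is undefined: all values coincide."""


class UndefinedMetricError(ThromboflowError):
    """A reported metric is undefined for this state (e.g. zero outlet flux)."""
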