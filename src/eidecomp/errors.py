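"""Exception hierarchy used across the package.

Everything derives from :class:`EidecompError` so callers can catch one base;
most classes also derive from the matching builtin (``ValueError`` etc.) so
generic handling keeps working.
"""


class EidecompError(Exception):
    """Base class for all package errors."""


class SchemaError(EidecompError, KeyError):
    """A file is missing required metadata or groups."""


class ShapeError(EidecompError, ValueError):
    """Traces that must share a length/timebase do not."""


class RangeError(EidecompError, ValueError):
    """A requested time window lies outside the recorded span."""


class ParameterError(EidecompError, ValueError):
    """A parameter violates its precondition (e.g. tau <= 0)."""


class InsufficientDataError(EidecompError, ValueError):
    """Not enough sweeps / samples / potentials for the operation."""


class DataError(EidecompError, ValueError):
    """Input data violates an invariant (non-finite samples, amax <= 0, ...)."""


class DegenerateFitError(EidecompError, ValueError):
    """The regressor is identically zero in the fit window."""


class UndefinedThresholdError(EidecompError, ValueError):
    """Baseline SD is zero and the trace never deviates: no threshold exists."""
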