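"""Exception hierarchy shared across the package."""


class SpatEdmError(Exception):
    """Base class for all package errors."""


class FormatError(SpatEdmError):
    """Input file does not match the expected tabular layout."""


class ValidationError(SpatEdmError):
    """A table or series violates a structural invariant."""


class AlignmentError(SpatEdmError):
    """Two series/tables do not share a compatible time grid."""


class EmptyDataError(SpatEdmError):
    """No usable records remain after filtering."""


class InsufficientDataError(SpatEdmError):
    """Too few points for the requested estimate."""


class DegenerateSeriesError(SpatEdmError):
    """A series has (numerically) zero variance where variance is required."""


class DegenerateGeometryError(SpatEdmError):
    """All state vectors coincide; distances carry no information."""


class InsufficientGridError(SpatEdmError):
    """Too few library sizes to run a convergence test."""


class ParameterError(SpatEdmError):
    """A generator or model parameter produces invalid dynamics."""
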