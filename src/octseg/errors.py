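"""Exception hierarchy for octseg.

All package errors derive from :class:`OctsegError` so callers can catch one
base class at CLI or pipeline boundaries.
"""


class OctsegError(Exception):
    """Base class for all octseg errors."""


class FormatError(OctsegError):
    """A file could not be parsed in the declared format."""


class MetadataError(OctsegError):
    """Required metadata (e.g. pixel spacing) is missing or malformed."""


class ValidationError(OctsegError):
    """A domain object violates one of its invariants."""


class BoundsError(OctsegError):
    """An index (frame, row, column) is out of range."""


class ParameterError(OctsegError):
    """A numeric parameter is outside its admissible range."""


class EndpointError(OctsegError):
    """No usable source/destination candidate in the image end bands."""


class ConstraintConflictError(OctsegError):
    """A must-pass pick refers to an excluded or non-existent candidate."""


class InfeasiblePathError(OctsegError):
    """No column-monotone path satisfies the waypoints."""


class SeedError(OctsegError):
    """Too few seed points to fit a boundary spline."""


class ComparabilityError(OctsegError):
    """Two boundaries are not comparable (layer/frame/width mismatch)."""


class DegenerateInputError(OctsegError):
    """A statistic is undefined on this input (e.g. all-zero differences)."""
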