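"""Exception hierarchy.

All domain errors derive from :class:`PpbnError` so callers can catch the
package's failures in one clause; they also derive from ``ValueError`` so
generic argument validation behaves as expected.
"""


class PpbnError(ValueError):
    """Base class for all domain errors raised by ppbn."""


class DegenerateImageError(PpbnError):
    """An image operation is undefined for this input (e.g. all-void image)."""


class DegenerateInputError(PpbnError):
    """A numeric input carries no usable signal (e.g. all-zero pressure points)."""


class ScaleUndefinedError(PpbnError):
    """The pressure-weight scale factor is undefined (first weight is zero)."""


class PreconditionError(PpbnError):
    """A documented precondition of the operation was violated."""


class ConflictError(PpbnError):
    """Prior and observation likelihood have disjoint support."""


class InfeasibleCalibrationError(PpbnError):
    """The requested stationary/shift-rate targets cannot be met under the mask."""


class InvalidTrainingSetError(PpbnError):
    """The training set is missing required posture labels."""


class ParseError(PpbnError):
    """A data file could not be parsed; the message names the offending line."""
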