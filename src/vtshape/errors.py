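"""Exception hierarchy for the vtshape pipeline."""


class VTShapeError(Exception):
    """Base class for all vtshape errors."""


class FormatError(VTShapeError):
    """A file could not be read or written in any supported dialect."""


class DimensionError(VTShapeError):
    """Array shapes are inconsistent with what an operation requires."""


class ValidationError(VTShapeError):
    """An input violates a documented precondition or contract."""


class DegenerateError(VTShapeError):
    """The input is structurally valid but degenerate (constant, empty, zero-length)."""


class NoPathError(VTShapeError):
    """The two path anchors are not connected within the search region."""


class EstimationError(VTShapeError):
    """A model (bias field, threshold) could not be estimated from the data."""
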