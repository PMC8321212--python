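"""Exception types shared across the package."""


class EdgeMetricsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EdgeMetricsError, ValueError):
    """An input violates a precondition (shapes, thresholds, parameters)."""


class DimensionMismatchError(ValidationError):
    """Ground truth and candidate maps have different pixel dimensions."""


class EmptyGroundTruthError(ValidationError):
    """The ground-truth map carries no contour point; every measure divides by |Gt|."""
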