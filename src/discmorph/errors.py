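"""Exception types shared across the pipeline."""


class DiscmorphError(Exception):
    """Base class for all package errors."""


class MaskError(DiscmorphError):
    """The binary segmentation mask violates its contract."""


class ContourError(DiscmorphError):
    """A boundary contour operation failed (self-intersection, bad anchors...)."""


class ConformalError(DiscmorphError):
    """The conformal map could not be solved or evaluated."""


class CrowdingError(ConformalError):
    """Prevertices collapsed below resolvable separation on the unit circle."""


class DegenerateImageError(DiscmorphError):
    """An image has zero intensity variance and cannot be correlated."""


class EstimatorError(DiscmorphError):
    """A nonparametric estimator received invalid input (ties, too few samples)."""


class ConfigError(DiscmorphError):
    """A run configuration is invalid."""
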