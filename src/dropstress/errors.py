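"""Exception hierarchy for the droplet stress pipeline."""


class DropstressError(Exception):
    """Base class for all package errors."""


class ParameterError(DropstressError, ValueError):
    """Invalid user-supplied parameter (negative dimension, bad mode, ...)."""


class SegmentationError(DropstressError):
    """Initial droplet segmentation failed (empty image, multiple components)."""


class ReconstructionError(DropstressError):
    """Point-cloud reconstruction failed (e.g. most edge fits rejected)."""


class GeometryError(DropstressError):
    """Degenerate surface geometry (zero area element, non-star-shaped chart)."""


class FitError(DropstressError):
    """A model fit (quadric, harmonic) produced an unusable result."""
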