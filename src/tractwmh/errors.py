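"""Exception hierarchy for the tractwmh pipeline.

Every stage raises a subclass of :class:`TractWMHError` so callers can
distinguish pipeline failures from programming errors.
"""


class TractWMHError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(TractWMHError):
    """Invalid phantom or pipeline configuration (e.g. grid too small)."""


class PlacementError(TractWMHError):
    """A lesion target volume cannot be placed inside its tract."""


class MaskError(TractWMHError):
    """A mask is empty, too small, or otherwise unusable."""


class ShapeError(TractWMHError):
    """Arrays that must share a voxel grid do not."""


class InputError(TractWMHError):
    """Input values violate a documented precondition."""


class DegenerateDistributionError(TractWMHError):
    """Intensity distribution has no variance; a Gaussian fit is meaningless."""


class MappingError(TractWMHError):
    """A region composition references a parcellation label that does not exist."""


class ReferenceRegionError(TractWMHError):
    """Reference-region uptake is zero or negative; SUVr is undefined."""


class EstimationError(TractWMHError):
    """A regression model cannot be estimated (rank deficiency, tiny n, ...)."""


class FormatError(TractWMHError):
    """A file is not in the expected on-disk format."""
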