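"""Exception hierarchy for the LGE pipeline."""


class LgeQuantError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(LgeQuantError, ValueError):
    """A numeric parameter violates its precondition (e.g. non-positive step)."""


class GeometryError(LgeQuantError, ValueError):
    """Invalid volume or slice geometry (non-orthonormal axes, bad spacing)."""


class ContourError(LgeQuantError, ValueError):
    """Degenerate or inconsistent contour polygons."""


class EmptyRoiError(LgeQuantError, ValueError):
    """An ROI contains no (or too few) pixel centers."""


class NoReferenceError(LgeQuantError, ValueError):
    """No slice in the stack carries the reference ROI the method needs."""


class StatsError(LgeQuantError, ValueError):
    """Agreement statistics cannot be computed (n too small, constant series)."""


class IoError(LgeQuantError, ValueError):
    """File format / geometry-tag problems when reading or writing images."""


class ConfigError(LgeQuantError, ValueError):
    """Invalid pipeline configuration."""
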