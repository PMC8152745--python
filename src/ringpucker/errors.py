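"""Exception hierarchy shared across the package."""


class RingPuckerError(Exception):
    """Base class for all package-specific errors."""


class TrajectoryParseError(RingPuckerError):
    """A trajectory file is malformed (wrong atom count, truncated block, bad token)."""


class ConfigurationError(RingPuckerError):
    """Inconsistent or missing configuration (ring spec, constants, topology)."""


class DegenerateGeometryError(RingPuckerError):
    """Geometry does not admit the requested quantity (collinear atoms etc.)."""


class RingClosureError(RingPuckerError):
    """Internal coordinates of a planar ring do not close into a polygon."""
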