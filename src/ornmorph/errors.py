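"""Exception types shared across the package."""


class OrnmorphError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(OrnmorphError):
    """Invalid geometric input (degenerate polygon, empty mesh, bad normal)."""


class WatertightError(GeometryError):
    """Operation requires a watertight, consistently oriented mesh."""


class ContainmentError(GeometryError):
    """Hollow-pair rule applied to an inner object not contained in the outer."""


class SkeletonError(OrnmorphError):
    """Malformed skeleton (cycles, duplicate ids, unexpected forest)."""


class AmbiguousRankError(OrnmorphError):
    """Neuron size ranks too close to call (tie within tolerance)."""


class StatisticsError(OrnmorphError):
    """Degenerate input to a statistical test (zero variance, n too small)."""
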