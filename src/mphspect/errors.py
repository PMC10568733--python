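"""Package-specific exception types."""


class MphSpectError(Exception):
    """Base class for all package errors."""


class PlacementError(MphSpectError):
    """A phantom structure or analysis VOI could not be placed as required."""


class DesignInfeasibleError(MphSpectError):
    """No collimator geometry satisfies the footprint and overlap constraints."""


class GeometryError(MphSpectError):
    """Inconsistent or degenerate acquisition geometry."""


class OrbitError(MphSpectError):
    """Invalid detector orbit (e.g. duplicate gantry angles)."""


class ScalingError(MphSpectError):
    """Count scaling is undefined (e.g. zero total input counts)."""


class DegenerateDataError(MphSpectError):
    """Input data admit no meaningful reconstruction (e.g. all-zero projections)."""


class UndefinedMetricError(MphSpectError):
    """An image-quality metric is undefined for the given inputs."""
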