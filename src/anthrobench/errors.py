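"""Exception hierarchy shared across the package."""


class AnthrobenchError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AnthrobenchError):
    """Invalid parameter, option, or run configuration."""


class LandmarkError(AnthrobenchError):
    """A required named landmark is missing or out of range."""


class GeometryError(AnthrobenchError):
    """Degenerate geometry: zero IPD, collinear foot points, bad orientation."""


class TopologyError(AnthrobenchError):
    """Mesh connectivity violates the watertightness contract."""

    def __init__(self, message: str, boundary_edges=None):
        super().__init__(message)
        self.boundary_edges = boundary_edges if boundary_edges is not None else []


class UnitsError(AnthrobenchError):
    """Operation applied to a mesh in the wrong unit system."""


class GenerationError(AnthrobenchError):
    """Synthetic-mesh parameters are geometrically infeasible."""
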