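"""Exception hierarchy for the lumbarlift pipeline."""


class LumbarLiftError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LumbarLiftError):
    """Inconsistent or invalid configuration values."""


class ParameterError(LumbarLiftError, ValueError):
    """A numeric parameter is out of its admissible range."""


class OutOfRangeError(LumbarLiftError, ValueError):
    """A query time or index falls outside the trial."""


class MissingMarkerError(LumbarLiftError, KeyError):
    """A required marker label is absent from a marker table."""


class DegenerateGeometryError(LumbarLiftError):
    """Geometry collapsed to a degenerate configuration (zero-length vector...)."""


class GeometryError(LumbarLiftError):
    """Parametric geometry cannot be realised (e.g. offset >= semi-axis)."""


class MeshingError(LumbarLiftError):
    """Tetrahedral meshing failed; carries the offending part when known."""


class MaterialBindingError(LumbarLiftError, KeyError):
    """A mesh part has no matching row in the material table."""


class ModelError(LumbarLiftError):
    """Load-case construction failed (empty node sets, bad magnitudes...)."""


class SegmentationError(LumbarLiftError):
    """Torque curve does not expose the two-peak structure needed for phases."""


class SingularSystemError(LumbarLiftError):
    """The assembled stiffness is singular (unconstrained rigid-body modes)."""


class SolverError(LumbarLiftError):
    """Static solve failed to reach the requested residual."""


class QueryError(LumbarLiftError, KeyError):
    """A stress-field or report query named an unknown/empty part."""


class DependencyError(LumbarLiftError):
    """A pipeline stage was requested before its upstream artifact exists."""


class ParseError(LumbarLiftError):
    """A delimited-text artifact could not be parsed; carries file context."""
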