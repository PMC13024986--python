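"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`WoundmetryError`, so callers can catch one type at a pipeline
boundary and still distinguish configuration mistakes from bad data.
"""


class WoundmetryError(Exception):
    """Base class for all errors raised by woundmetry."""


class MeshReadError(WoundmetryError):
    """A mesh file is missing or cannot be parsed."""


class UnsupportedFormatError(WoundmetryError):
    """A mesh format other than PLY/OBJ/STL was requested."""


class EmptyMeshError(WoundmetryError):
    """Validation removed every face of a mesh."""


class EmptySelectionError(WoundmetryError):
    """A region-of-interest operation selected no faces."""


class ConfigurationError(WoundmetryError):
    """A selection pathway was requested on a mesh lacking the needed channel."""


class DomainError(WoundmetryError, ValueError):
    """A metric was called with an out-of-domain argument (e.g. BSA <= 0)."""


class InsufficientDataError(WoundmetryError):
    """A longitudinal metric needs more observations than the series has."""


class SchemaError(WoundmetryError):
    """A tabular input is missing required columns or has unparsable values."""


class AnnotationError(WoundmetryError):
    """A cohort grouping refers to an unknown annotation label."""


class GeometryError(WoundmetryError):
    """A synthetic wound patch does not fit inside its anatomy."""


class TrajectoryResolutionError(WoundmetryError):
    """A target wound area is too small to represent at the mesh resolution."""
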