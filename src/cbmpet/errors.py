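"""Exception hierarchy for the cbmpet pipeline.

Every failure mode named by an operation contract maps to one of these, so
callers (and the CLI) can distinguish malformed inputs from scientific
degeneracies without string matching.
"""


class CbmpetError(Exception):
    """Base class for all cbmpet errors."""


class FormatError(CbmpetError):
    """A file is not a valid instance of its declared format."""


class ShapeError(CbmpetError):
    """Array lengths or mesh/field associations are inconsistent."""


class GeometryError(CbmpetError):
    """Grids, warps or meshes are geometrically incompatible."""


class ValidationError(CbmpetError):
    """A configuration value is outside its permitted range."""


class ReferenceRegionError(CbmpetError):
    """The cerebellum reference region is empty or non-positive."""


class CohortError(CbmpetError):
    """Too few subjects for the requested group statistic."""


class ConsistencyError(CbmpetError):
    """Two pipeline stages were run with incompatible settings."""


class DegenerateModelError(CbmpetError):
    """A model has no usable signal (e.g. no gray or white matter)."""


class UndefinedStatisticError(CbmpetError):
    """A statistic is mathematically undefined for the given input."""


class AmbiguityError(CbmpetError):
    """An exhaustive search found more than one equally good solution."""
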