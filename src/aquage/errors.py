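"""Exception hierarchy for aquage.

All package errors derive from :class:`AquageError` so callers can catch one
base class at pipeline boundaries.
"""


class AquageError(Exception):
    """Base class for all aquage errors."""


class UndefinedResultError(AquageError):
    """A ratio or statistic is mathematically undefined for these inputs."""


class OutOfRangeError(AquageError):
    """An input violates a physical range constraint (e.g. ICC > TCC)."""


class ParameterError(AquageError):
    """An option value is invalid (e.g. even median kernel)."""


class InsufficientDataError(AquageError):
    """A window or pairing contains no usable measurements."""


class InsufficientDepthError(AquageError):
    """A z-stack has too few slices for the requested base-slice removal."""


class SchemaError(AquageError):
    """An input file does not match the expected column/key schema."""


class ParseError(AquageError):
    """A field in an input file could not be parsed."""


class FormatError(AquageError):
    """An image file has an unexpected page/channel layout."""


class SimulationError(AquageError):
    """A synthetic scenario is infeasible (e.g. bulk concentration < 0)."""
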