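"""Exception hierarchy used across the package."""


class CellTracksError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CellTracksError):
    """A user-supplied configuration (column map, run config) is invalid."""


class IntegrityError(CellTracksError):
    """Input data violate a structural invariant (duplicate keys, dangling refs)."""


class FormatError(CellTracksError):
    """A file could not be parsed in the declared format."""


class DegenerateVarianceError(CellTracksError):
    """Pooled standard deviation is zero while the group means differ."""


class DimensionalityError(CellTracksError):
    """Operation only supports 2-D + time data."""


class DependencyError(CellTracksError):
    """A pipeline step was invoked before its prerequisite artifact exists."""
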