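"""Exception hierarchy for gzmorph."""


class GzMorphError(Exception):
    """Base class for all gzmorph errors."""


class ConfigError(GzMorphError, ValueError):
    """A generator configuration violates its invariants."""


class DomainError(GzMorphError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class GeometryError(GzMorphError, ValueError):
    """A geometric input is degenerate (too few vertices, empty path, ...)."""


class LandmarkError(GzMorphError, ValueError):
    """A required landmark is missing from a cell field."""


class SchemaError(GzMorphError, ValueError):
    """A file does not match the expected column schema."""


class DegenerateFitError(GzMorphError, ValueError):
    """A regression or decomposition cannot be computed from the input."""


class DegenerateColumnError(DegenerateFitError):
    """A column is constant and cannot be standardized."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"column {column!r} is constant and cannot be standardized")


class GroupingError(GzMorphError, ValueError):
    """A group structure is too small or degenerate for the requested test."""
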