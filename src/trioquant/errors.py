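"""Exception types shared across the pipeline."""


class TrioquantError(Exception):
    """Base class for all package errors."""


class GeometryError(TrioquantError):
    """A parcellation or polygon operation produced invalid geometry."""


class ConfigError(TrioquantError):
    """A configuration value violates its invariants."""


class SchemaError(TrioquantError):
    """An input file does not match the expected schema."""


class RankDeficiencyError(TrioquantError):
    """Landmark configuration is degenerate (collinear or too few points)."""


class EmptyExperimentError(TrioquantError):
    """An operation requires at least one counted cell."""


class InsufficientDataError(TrioquantError):
    """Too few observations for the requested estimate."""
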