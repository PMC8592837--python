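"""Exception types shared across the package."""


class SpatialImmuneError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpatialImmuneError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(SpatialImmuneError, ValueError):
    """A table is missing required columns or violates the documented CSV schema."""


class ValidationError(SpatialImmuneError, ValueError):
    """Row- or value-level validation failure (non-finite coordinate, bad enum, ...)."""


class DegenerateDataError(SpatialImmuneError, ValueError):
    """Input is degenerate for the requested operation (e.g. all-equal 1-D clustering)."""


class PipelineStageError(SpatialImmuneError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
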