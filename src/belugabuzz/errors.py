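"""Exception types shared across the pipeline."""


class BelugabuzzError(ValueError):
    """Base class for all package-specific errors."""


class DegenerateTrainError(BelugabuzzError):
    """Click train too short to support the requested computation."""


class InputOrderError(BelugabuzzError):
    """Click peak times are not strictly increasing."""


class DegenerateScalingError(BelugabuzzError):
    """A feature column has zero variance and cannot be standardized."""


class ConfigError(BelugabuzzError):
    """Invalid clustering configuration (distance/linkage pairing or k)."""


class NoSplitError(BelugabuzzError):
    """Decision stump cannot split single-class data."""


class NoRunError(BelugabuzzError):
    """Predicted fish-count series is identically zero; no run to summarize."""


class SchemaError(BelugabuzzError):
    """Input table is missing a required column."""


class RowError(BelugabuzzError):
    """One or more input rows failed to parse (line numbers in message)."""


class GenerationError(BelugabuzzError):
    """Synthetic-data generator asked for an infeasible configuration."""
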