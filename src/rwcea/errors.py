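"""Exception hierarchy for the rwcea package."""


class RwceaError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RwceaError):
    """An invalid simulation or analysis configuration value; names the field."""


class SchemaError(RwceaError):
    """A cohort file violates the documented CSV schema."""


class SeparationError(RwceaError):
    """Perfect separation in the propensity model; advise removing a covariate."""


class ConvergenceError(RwceaError):
    """The propensity model failed to converge within the iteration budget."""


class IdentifiabilityError(RwceaError):
    """The censoring survivor hits zero where an inverse weight is required."""
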