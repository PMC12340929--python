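"""Exception hierarchy shared across the toolkit."""


class CortexPhenoError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CortexPhenoError):
    """A simulation or run configuration parameter is invalid."""


class SchemaError(CortexPhenoError):
    """A table is missing required columns or has malformed values."""


class DesignError(CortexPhenoError):
    """A statistical design is degenerate (missing level, rank deficient...)."""


class PopulationNotFoundError(CortexPhenoError, KeyError):
    """Requested cell population does not exist at the stated level."""


class UndefinedStatisticError(CortexPhenoError):
    """A statistic is undefined for the given input (e.g. burden with no expressed genes)."""
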