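"""Exception hierarchy used across the package."""


class MixgutsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MixgutsError):
    """A delimited-text table does not have the expected layout."""


class ValidationError(MixgutsError):
    """Data violate an invariant (e.g. increasing survivor counts)."""


class ConfigurationError(MixgutsError):
    """A run is mis-specified (missing parameter, unknown model label...)."""


class DomainError(MixgutsError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class UsageError(MixgutsError):
    """An operation was called in a context where it is not defined."""


class InsufficientConfidenceError(MixgutsError):
    """Every deviation point was masked for excessive uncertainty."""


class MCMCError(MixgutsError):
    """Sampler failure; carries partial output when available."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial
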