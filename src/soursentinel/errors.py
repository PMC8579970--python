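"""Exception types shared across the package."""


class SoursentinelError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SoursentinelError, ValueError):
    """Cross-table or schema consistency failure in input data."""


class DomainError(SoursentinelError, ValueError):
    """An operation was called on mathematically inadmissible input."""


class ConfigError(SoursentinelError, ValueError):
    """Invalid generator or pipeline configuration."""
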