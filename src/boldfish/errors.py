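"""Exception hierarchy shared across the package."""


class BoldfishError(Exception):
    """Base class for all package-specific errors."""


class DomainError(BoldfishError, ValueError):
    """A numeric argument lies outside its mathematical domain."""


class InvalidStateError(BoldfishError, ValueError):
    """A state object violates one of its structural invariants."""


class ConfigurationError(BoldfishError, ValueError):
    """A run configuration, schedule or success table is inconsistent.

    The message lists every offending key, one per line, so a user can fix
    a configuration file in a single pass.
    """


class UnsupportedVariantError(BoldfishError, TypeError):
    """An operation was applied to a model variant it is not defined for."""
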