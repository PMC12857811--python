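"""Exception hierarchy shared across the package."""


class SaaError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SaaError, ValueError):
    """A numeric or enum parameter is out of its valid range."""


class InputError(SaaError, ValueError):
    """Input data (traces, calls, tables) violate a precondition."""


class SchemaError(SaaError, ValueError):
    """A tabular file is missing required columns or has a bad layout."""


class ValidationError(SaaError, ValueError):
    """Records fail cohort/result validation (e.g. duplicate keys)."""


class IntegrityError(SaaError, RuntimeError):
    """Packaged reference data are corrupt."""


class ConfigurationError(SaaError, ValueError):
    """A rule set or run configuration is internally inconsistent."""


class UsageError(SaaError, ValueError):
    """An operation was invoked in a way its contract forbids."""
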