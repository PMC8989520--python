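"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (usage 2, validation 3, empty input 4).
"""


class RetrotermError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RetrotermError):
    """A configuration value is missing or inconsistent (bad preset, bad path)."""


class ValidationError(RetrotermError):
    """Input data violates a documented invariant (bounds, alphabet, schema)."""


class EmptyInputError(RetrotermError):
    """An operation that needs at least one record received none."""


class EmptyProfileError(EmptyInputError):
    """A profile was requested for a sample with zero usable reads."""


class UndefinedRatioError(ValidationError):
    """A ratio metric has a zero denominator; carries the offending context."""
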