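"""Exception hierarchy shared by all lungstress modules."""


class LungStressError(Exception):
    """Base class for all package-specific errors."""


class DomainError(LungStressError, ValueError):
    """An input is outside the physical domain of a formula (e.g. negative volume)."""


class UsageError(LungStressError, ValueError):
    """An operation was called in a way its contract forbids (e.g. missing delta_p)."""


class InconsistencyError(LungStressError, ValueError):
    """Mutually supplied inputs contradict each other (e.g. shunt exceeding admixture)."""


class SchemaError(LungStressError, ValueError):
    """A patient table or config file does not match the documented schema."""


class ConfigError(LungStressError, ValueError):
    """An invalid configuration value (e.g. a negative composite-score weight)."""


class PlausibilityWarning(UserWarning):
    """A value is physically admissible but outside the expected clinical range."""
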