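"""Exception hierarchy for the userlift package."""


class UserLiftError(Exception):
    """Base class for all package errors."""


class ConfigError(UserLiftError, ValueError):
    """A configuration value violates a documented bound."""


class SchemaError(UserLiftError, ValueError):
    """An input table does not match the documented schema."""


class ValidationError(UserLiftError, ValueError):
    """A row-level value is outside its permitted range."""


class ContractError(UserLiftError, ValueError):
    """Caller violated an interface contract (mismatched lengths, units, user sets)."""


class EmptyCohortError(UserLiftError, ValueError):
    """No participant survived the inclusion filters."""
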