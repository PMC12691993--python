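"""Exception hierarchy shared across the package."""


class ShuntLedgerError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ShuntLedgerError):
    """A file does not parse against the documented schema."""


class ValidationError(ShuntLedgerError):
    """A parsed object violates an invariant (element balance, thresholds...)."""


class ConfigurationError(ShuntLedgerError):
    """A rule table, profile, or run configuration is inconsistent."""


class SearchSpaceError(ShuntLedgerError):
    """An exhaustive search would exceed its documented limits; refused outright."""
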