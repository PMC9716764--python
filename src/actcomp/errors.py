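"""Exception hierarchy shared across the package."""


class ActcompError(Exception):
    """Base class for all package-specific errors."""


class AccelParseError(ActcompError):
    """An epoch CSV file could not be parsed (row numbers are 1-based)."""


class DataError(ActcompError):
    """Input data violate a precondition of an operation."""


class ConfigError(ActcompError):
    """A configuration mapping is missing a key or holds an invalid value."""
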