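"""Exception hierarchy shared across the package."""


class WcMaldiError(Exception):
    """Base class for all package errors."""


class ParseError(WcMaldiError):
    """A file could not be parsed; the message names the offending location."""


class ConfigError(WcMaldiError):
    """Invalid configuration value or structure (CLI exit code 2)."""


class DataError(WcMaldiError):
    """Input data violates a contract (CLI exit code 3)."""
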