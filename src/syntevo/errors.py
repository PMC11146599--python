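"""Exception hierarchy."""


class SyntevoError(Exception):
    """Base class for all package errors."""


class ConfigError(SyntevoError):
    """Invalid configuration value."""


class InputError(SyntevoError):
    """Invalid or inconsistent input data."""


class ParseError(SyntevoError):
    """Malformed input file."""


class ConsistencyError(SyntevoError):
    """Internal invariant violated (indicates a bug upstream)."""
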