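"""Shared exception types."""


class ConfigurationError(ValueError):
    """Raised when user-supplied parameters or references are invalid."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; message names the line."""
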