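"""Exception types shared across the package."""


class DpannkitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DpannkitError, ValueError):
    """An input value violates a documented precondition."""


class ParseError(DpannkitError, ValueError):
    """A file could not be parsed; the message names the offending row/column."""
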