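"""Exception types shared across the package."""


class GenoverlapError(Exception):
    """Base class for all package errors."""


class ParseError(GenoverlapError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class ValidationError(GenoverlapError, ValueError):
    """Input parsed but violates a domain invariant."""
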