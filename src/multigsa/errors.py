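"""Exception hierarchy."""


class MultigsaError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(MultigsaError):
    """A request or dataset violates a hard precondition."""


class ParseError(MultigsaError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class AnalysisError(MultigsaError):
    """A computation cannot proceed on the given (otherwise valid) input."""
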