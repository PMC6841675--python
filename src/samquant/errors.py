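"""Exception types shared across the package."""


class SamQuantError(Exception):
    """Base class for all package errors."""


class ValidationError(SamQuantError, ValueError):
    """An input value violates a documented precondition; names the offending field."""


class DegenerateGeometryError(SamQuantError, ValueError):
    """A geometric construction is undefined for this input (rank deficiency,
    coincident seeds, zero-length direction, ...)."""


class DegenerateNormalizationError(SamQuantError, ValueError):
    """Min-max normalization of a constant field is undefined."""


class ParseError(SamQuantError, ValueError):
    """A file could not be parsed; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
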