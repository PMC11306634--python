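"""Exception types shared across the package."""


class MolComplexityError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(MolComplexityError, ValueError):
    """An argument violates a documented precondition."""


class EncodingError(MolComplexityError, ValueError):
    """Text could not be encoded; carries the offending character index."""

    def __init__(self, message: str, index: int):
        super().__init__(f"{message} (character index {index})")
        self.index = index


class ParseError(MolComplexityError, ValueError):
    """A file could not be parsed; carries the 1-based line (or row) number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"{message} (line {line})")
        self.line = line


class UndefinedInputError(MolComplexityError, ValueError):
    """The requested quantity is undefined for this input (e.g. empty sequence)."""


class DegenerateInputError(MolComplexityError, ValueError):
    """A statistic is undefined because an input is degenerate (e.g. constant)."""


class InsufficientDataError(MolComplexityError, ValueError):
    """Too few complete observations to compute the requested statistic."""
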