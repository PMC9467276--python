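"""Exception types shared across the toolkit."""


class BalfkitError(Exception):
    """Base class for all balfkit errors."""


class ParseError(BalfkitError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class StructureError(BalfkitError):
    """Structurally inconsistent input (dangling references, broken hierarchy)."""


class FormatError(BalfkitError):
    """File contents violate the format contract (dimensions, value domain)."""


class ArgumentError(BalfkitError, ValueError):
    """Invalid argument to an operation."""


class DegenerateInputError(BalfkitError):
    """Input that is technically well-formed but unusable (e.g. an all-zero cell)."""
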