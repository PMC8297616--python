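"""Exception hierarchy shared across the package."""


class TwoStepError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(TwoStepError, ValueError):
    """A configuration object violates its invariants."""


class InvalidInputError(TwoStepError, ValueError):
    """A function argument or data record is malformed or out of range."""


class UndefinedCellError(TwoStepError):
    """A stay-table cell has no observations, so a score cannot be formed.

    Carries the offending cell names so callers can report *which* condition
    was never observed rather than silently imputing zero.
    """

    def __init__(self, cells):
        self.cells = tuple(cells)
        super().__init__(
            "stay percentage undefined for cell(s) with no observations: "
            + ", ".join(self.cells)
        )


class ParseError(TwoStepError, ValueError):
    """A data file could not be parsed; carries a line number when known."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(TwoStepError, ValueError):
    """A parsed record is internally inconsistent (e.g. transition label)."""
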