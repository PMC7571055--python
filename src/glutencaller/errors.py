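"""Exception hierarchy shared across the package."""


class GlutenCallerError(Exception):
    """Base class for all errors raised by glutencaller."""


class ValidationError(GlutenCallerError, ValueError):
    """An input value violates a precondition."""


class SchemaError(GlutenCallerError):
    """A fixture or input table is malformed.

    Carries enough context (file, row, column) to locate the offending cell.
    """

    def __init__(self, message, *, file=None, row=None, column=None):
        parts = [message]
        if file is not None:
            parts.append(f"file={file}")
        if row is not None:
            parts.append(f"row={row}")
        if column is not None:
            parts.append(f"column={column}")
        super().__init__("; ".join(str(p) for p in parts))
        self.file = file
        self.row = row
        self.column = column


class UnknownAlleleError(GlutenCallerError, KeyError):
    """Lookup of a subunit name that is not in the reference library."""


class ParseError(GlutenCallerError):
    """A delimited text file could not be parsed."""

    def __init__(self, message, *, file=None, line=None):
        loc = f" ({file}:{line})" if file is not None else ""
        super().__init__(f"{message}{loc}")
        self.file = file
        self.line = line


class CalibrationError(ValidationError):
    """External-standard calibration outside the accepted scale range."""


class DiscordanceError(GlutenCallerError):
    """Replicates of one sample disagree on the genotype call."""

    def __init__(self, message, details=None):
        super().__init__(message)
        self.details = details or []
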