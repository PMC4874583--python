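"""Exception hierarchy.

Schema/dataset errors map to CLI exit code 2, parameter errors to 3.
"""


class CisGraphError(Exception):
    """Base class for all package errors."""


class SchemaError(CisGraphError):
    """A mandatory column is missing or unresolvable."""


class RowError(CisGraphError):
    """A single input row is malformed (carries the 1-based row number)."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class DatasetError(CisGraphError):
    """The dataset as a whole is unusable (e.g. empty file)."""


class ParameterError(CisGraphError):
    """An argument violates its domain (threshold < 1, dimension > G, ...)."""


class ContractError(CisGraphError):
    """An internal precondition was violated (unsorted input, bad counts)."""
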