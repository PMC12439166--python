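"""Exception hierarchy shared across the package."""


class FlavokitError(Exception):
    """Base class for all package-specific errors."""


class SpecValidationError(FlavokitError, ValueError):
    """A generator or run spec violates its invariants.

    The offending field name is stored in ``field``.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class PlacementError(FlavokitError, RuntimeError):
    """Random molecule placement failed within the retry budget."""


class InsufficientDataError(FlavokitError, ValueError):
    """Too few distinct observations to attempt a fit or test."""


class DegenerateScaleError(FlavokitError, ValueError):
    """A scale estimate (standard deviation) is undefined (fewer than 2 values)."""


class SchemaError(FlavokitError, ValueError):
    """A tabular input is missing a required column."""


class IntegrityError(FlavokitError, ValueError):
    """A structural consistency check failed (duplicate keys, broken lineage)."""


class ParseError(FlavokitError, ValueError):
    """A file could not be parsed; carries the 1-based row/line number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")
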