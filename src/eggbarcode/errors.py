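"""Exception hierarchy.

Input/contract problems derive from :class:`InputError` (CLI exit code 2);
violated internal invariants raise :class:`InvariantError` (exit code 3).
"""


class EggBarcodeError(Exception):
    """Base class for all package errors."""


class InputError(EggBarcodeError):
    """User-supplied data or configuration violates a precondition."""


class ParseError(InputError):
    """A file could not be parsed; message names the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UndefinedIdentityError(EggBarcodeError):
    """Percent identity is undefined: no comparable alignment columns."""


class SaturatedDistanceError(EggBarcodeError):
    """K2P distance undefined: substitution saturation (log of non-positive)."""


class ConsistencyError(InputError):
    """Counts or tables contradict each other (e.g. more high-quality
    sequences than selected specimens)."""


class InvariantError(EggBarcodeError):
    """An internal invariant failed; indicates a bug, not bad input."""
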