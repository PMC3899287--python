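"""Exception hierarchy shared across the package.

Validation problems (bad symbols, bad shapes, bad references) and data-capacity
problems (not enough material to sample from) are kept distinct so the CLI can
map them to different exit codes.
"""


class AptapairError(Exception):
    """Base class for all package errors."""


class FormatError(AptapairError):
    """A file could not be parsed in the declared format."""


class ValidationError(AptapairError):
    """A record or value violates a domain invariant."""


class SequenceAlphabetError(ValidationError):
    """A sequence contains a symbol outside its canonical alphabet."""

    def __init__(self, record_id: str, position: int, symbol: str, alphabet: str):
        self.record_id = record_id
        self.position = position
        self.symbol = symbol
        super().__init__(
            f"record {record_id!r}: invalid symbol {symbol!r} at position "
            f"{position} (allowed: {alphabet})"
        )


class ReferentialIntegrityError(ValidationError):
    """A pair references an aptamer or target id that does not exist."""


class CapacityError(AptapairError):
    """Not enough distinct items exist to satisfy a sampling request."""


class StratificationError(AptapairError):
    """A class is too small to stratify into the requested partition."""


class DegenerateScaleError(ValidationError):
    """A property scale is constant and cannot be standardized."""
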