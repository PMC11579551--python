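"""Exception hierarchy shared across mtminer."""


class MTMinerError(Exception):
    """Base class for all mtminer errors."""


class ValidationError(MTMinerError, ValueError):
    """A data object violates one of its invariants."""


class ParseError(MTMinerError, ValueError):
    """A packaged or user-supplied text file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SequenceAlphabetError(ValidationError):
    """A sequence contains characters outside the 20-letter amino-acid alphabet."""

    def __init__(self, offending: set[str]):
        self.offending = offending
        super().__init__(
            "non-amino-acid characters in sequence: "
            + ", ".join(repr(c) for c in sorted(offending))
        )


class NoMTDomainError(MTMinerError):
    """No MT domain was found in any input protein."""


class AmbiguousArchitectureError(MTMinerError, ValueError):
    """Domain hits of different families overlap; architecture is undefined."""
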