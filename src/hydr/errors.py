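"""Exception types shared across the package."""


class HydrError(Exception):
    """Base class for package errors."""


class ParseError(HydrError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(HydrError, ValueError):
    """An object violates one of its invariants."""


class DomainError(HydrError, ValueError):
    """An argument is outside the physically meaningful domain."""


class RangeError(HydrError, ValueError):
    """A query falls outside the supported range (e.g. extrapolation)."""


class InsufficientDataError(HydrError):
    """Too few observations for the requested fit."""


class UnidentifiableError(HydrError):
    """The affected-water number cannot be fixed by non-negativity.

    Raised when the derivative spectrum has no negative region, so the
    affected spectrum stays non-negative for arbitrarily small N and the
    caller must supply N explicitly.
    """


class GenerationError(HydrError):
    """Synthetic-data generation failed (e.g. overfilled box)."""


class StageError(HydrError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
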