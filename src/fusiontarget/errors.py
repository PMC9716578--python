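"""Exception types shared across the package."""


class FusionTargetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(FusionTargetError):
    """A file could not be parsed; the message names the offending record."""


class ValidationError(FusionTargetError):
    """An in-memory object violates its invariants."""


class GenerationError(FusionTargetError):
    """Synthetic-data generation failed (e.g. rejection sampling exhausted)."""


class MalformedIntervalError(ValidationError):
    """A genomic interval has start >= end."""
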