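"""Exception types shared across the package."""


class PhenoQCError(Exception):
    """Base class for package errors."""


class InvalidScheduleError(PhenoQCError, ValueError):
    """A sampling schedule violates its invariants (e.g. non-positive f or d)."""


class OrderingError(PhenoQCError, ValueError):
    """Timestamps passed to a segmentation routine are not sorted."""


class DataIntegrityError(PhenoQCError, ValueError):
    """Event timestamps are mutually inconsistent (e.g. viewed before delivered)."""


class ValidationError(PhenoQCError, ValueError):
    """An input value is outside its allowed range (e.g. Likert response > 3)."""


class JoinError(PhenoQCError, ValueError):
    """Tables that must share subject identifiers do not."""


class EstimationError(PhenoQCError, RuntimeError):
    """A model cannot be estimated from the data provided."""
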