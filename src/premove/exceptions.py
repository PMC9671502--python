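"""Exception hierarchy for the premove pipeline."""


class PremoveError(Exception):
    """Base class for all package errors."""


class ValidationError(PremoveError, ValueError):
    """An object violates one of its declared invariants."""


class FormatError(PremoveError, ValueError):
    """An on-disk container is malformed (missing group, bad columns, ...)."""


class ParameterError(PremoveError, ValueError):
    """An operation was called with parameters outside its domain."""


class InsufficientDataError(PremoveError, ValueError):
    """Too few trials / events / samples for the requested computation."""


class FeasibilityError(PremoveError, RuntimeError):
    """A randomized placement could not be satisfied within bounded retries."""


class DegenerateDataError(PremoveError, ValueError):
    """Input is degenerate (zero variance, undefined baseline, flat hull...)."""
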