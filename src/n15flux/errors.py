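"""Exception hierarchy for the flux-processing pipeline."""


class N15FluxError(Exception):
    """Base class for all package errors."""


class InvalidRecordError(N15FluxError):
    """An ion-current record violates its invariants (e.g. I_light <= 0)."""


class InvalidReferenceError(N15FluxError):
    """A reference-gas record is unusable (e.g. all currents zero)."""


class DomainError(N15FluxError, ValueError):
    """An argument is outside its mathematical domain."""


class BelowDetectionError(N15FluxError):
    """Signal is at or below the background / detection limit.

    Raised instead of returning a clipped estimate so callers must flag
    the closure rather than silently zeroing it.
    """


class InconsistentInputError(N15FluxError):
    """Inputs are mutually inconsistent with the mixing model (e.g. d > 1)."""


class InsufficientDataError(N15FluxError):
    """Fewer usable data points than the operation requires."""


class DegenerateDesignError(N15FluxError):
    """Regression design matrix is degenerate (no spread in time)."""


class UndefinedRatioError(N15FluxError, ZeroDivisionError):
    """A ratio with a zero denominator was requested."""


class ConfigError(N15FluxError, ValueError):
    """A configuration object failed validation.

    Parameters
    ----------
    problems:
        Mapping or list of offending keys with messages.
    """

    def __init__(self, problems):
        self.problems = problems
        super().__init__(f"invalid configuration: {problems}")
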