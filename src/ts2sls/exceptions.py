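"""Exception hierarchy for the ts2sls package."""


class TS2SLSError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(TS2SLSError, ValueError):
    """Malformed input data or an inconsistent role mapping."""


class UnderIdentifiedError(ValidationError):
    """Fewer instruments than exposures (kz < kx)."""


class SingularMatrixError(TS2SLSError, ValueError):
    """A matrix that must be inverted is (numerically) rank deficient."""


class ConvergenceError(TS2SLSError, RuntimeError):
    """An iterative solver failed to converge.

    Carries the last iterate and the criterion history so the failure can
    be inspected.
    """

    def __init__(self, message, last_iterate=None, history=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.history = history
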