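"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`EyosvrError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class EyosvrError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(EyosvrError):
    """A configuration value is missing, unknown, or inconsistent."""


class ValidationError(EyosvrError):
    """An input violates a precondition (bad ids, non-finite values, ...)."""


class GenerationError(EyosvrError):
    """The synthetic-data generator could not satisfy the requested design."""


class HarmonizationError(EyosvrError):
    """Reference scaling failed (zero-variance feature, unknown subject, ...)."""


class FeatureMismatchError(EyosvrError):
    """Feature registries of two objects do not line up."""

    def __init__(self, message: str, missing=(), extra=()):
        super().__init__(message)
        self.missing = tuple(sorted(missing))
        self.extra = tuple(sorted(extra))


class LeakageError(EyosvrError):
    """A cross-validation audit found a held-out subject used in training."""


class ConvergenceError(EyosvrError):
    """An iterative fit did not converge after all fallback optimizers."""
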