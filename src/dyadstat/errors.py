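"""Exception hierarchy shared across dyadstat modules."""


class DyadstatError(Exception):
    """Base class for all dyadstat errors."""


class ValidationError(DyadstatError, ValueError):
    """Input data violates a documented precondition (range, shape, schema)."""


class ConfigurationError(DyadstatError, ValueError):
    """A scale definition, model spec, or study config is internally inconsistent."""


class UndefinedResultError(DyadstatError, ArithmeticError):
    """The requested statistic is mathematically undefined for this input
    (e.g. zero total variance in a reliability computation, no discordant
    pairs in a McNemar test)."""


class EstimationError(DyadstatError, RuntimeError):
    """Model estimation failed: non-convergence, infeasible sample size,
    or a non-positive-definite sample covariance matrix."""
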