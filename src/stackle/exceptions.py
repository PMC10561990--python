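"""Exception hierarchy for stackle.

All errors raised deliberately by the package derive from :class:`StackleError`,
so callers can distinguish configuration/input mistakes from genuine bugs.
"""


class StackleError(Exception):
    """Base class for all stackle errors."""


class ConfigurationError(StackleError, ValueError):
    """A learner roster, hyperparameter table or run configuration is invalid."""


class InputError(StackleError, ValueError):
    """A data matrix or response vector violates a precondition."""


class PredictionError(StackleError, RuntimeError):
    """Prediction cannot proceed (e.g. every fold model of a required learner failed)."""


class UndefinedMetricError(StackleError, ValueError):
    """A metric is mathematically undefined for the given inputs.

    Raised instead of silently returning 0 or NaN, e.g. Pearson correlation of a
    constant vector, or Cohen's kappa when both vectors are the same constant label.
    """
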