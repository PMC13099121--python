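"""Package-wide exception types."""


class GaoofError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GaoofError, ValueError):
    """An invalid configuration value (probability out of range, non-PSD
    correlation matrix, population smaller than the tournament, ...)."""


class ConvergenceError(GaoofError, RuntimeError):
    """An iterative search failed (e.g. the prevalence-matching intercept
    bisection cannot bracket the target)."""


class DegenerateFeatureError(GaoofError, ValueError):
    """A feature cannot be preprocessed: fully missing in the training fold,
    or zero variance after imputation. The message names the feature."""


class SchemaError(GaoofError, ValueError):
    """A table or rule set does not match the expected schema (unknown
    indicator, duplicated id, feature-set mismatch, ...)."""


class StratificationError(GaoofError, ValueError):
    """Stratified folds cannot be built: a class has fewer members than the
    number of folds."""
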