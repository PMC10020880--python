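"""Exception hierarchy shared across the package."""


class LungIntervalError(Exception):
    """Base class for package errors."""


class ConfigurationError(LungIntervalError):
    """Bad configuration: missing columns, invalid parameters, malformed dialects."""


class DataError(LungIntervalError):
    """Invalid data values: out-of-range probabilities, unknown categories, duplicates."""


class FitError(LungIntervalError):
    """Model fitting failed (separation, one-class outcomes, empty folds)."""
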