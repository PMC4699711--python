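"""Exception hierarchy shared across the pipeline stages."""


class BenpipeError(Exception):
    """Base class for all benpipe errors."""


class ParameterError(BenpipeError, ValueError):
    """An operation was called with an invalid parameter value."""


class DataError(BenpipeError, ValueError):
    """Input data violates a structural precondition (shape, finiteness, ...)."""


class DesignError(BenpipeError, ValueError):
    """A regression design matrix is unusable (e.g. rank deficient)."""


class ConfigurationError(BenpipeError, ValueError):
    """A run or cohort configuration is internally inconsistent."""


class DomainError(BenpipeError, ValueError):
    """A transform was requested outside its mathematical domain."""


class PipelineOrderError(BenpipeError, RuntimeError):
    """Preprocessing steps were applied in a forbidden order."""


class FormatError(BenpipeError, ValueError):
    """A file on disk is not in the expected format."""
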