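"""Exception hierarchy shared across the package."""


class RgnbError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RgnbError):
    """A delimited-text input violates the expected layout (duplicate ids, bad header)."""


class ValidationError(RgnbError):
    """Data content violates an invariant (negative/fractional counts, non-finite values)."""


class AlignmentError(RgnbError):
    """Sample-id sets of counts/covariates/labels cannot be reconciled."""


class ModelIOError(RgnbError):
    """Model (de)serialization failed: wrong schema version or corrupted payload."""


class FilterError(RgnbError):
    """A filtering step removed every gene."""


class FitError(RgnbError):
    """Preconditions for model fitting are not met."""


class PredictionError(RgnbError):
    """Test data incompatible with the fitted model."""


class DomainError(RgnbError):
    """Numeric argument outside the mathematical domain of an operation."""
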