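"""Named error classes.

Every malformed input is rejected with one of these; nothing is silently
coerced. Catch :class:`CoarseCauseError` to handle any package error.
"""


class CoarseCauseError(Exception):
    """Base class for all package errors."""


class ValidationError(CoarseCauseError):
    """Base class for input-validation failures."""


class MissingDataError(ValidationError):
    """A cell in the outcome, treatment, or covariate table is missing."""


class TreatmentCodingError(ValidationError):
    """The treatment column is not coded 0/1 with both arms present."""


class RoleError(ValidationError):
    """Column roles are missing, duplicated, or refer to absent columns."""


class ConfigError(ValidationError):
    """A configuration value is out of its allowed range."""


class FinitenessError(CoarseCauseError):
    """A quantity required to be finite is NaN or infinite."""


class EstimationImpossibleError(CoarseCauseError):
    """No stratum retains both treatment arms; nothing can be estimated."""


class StrataError(CoarseCauseError):
    """A strata-builder precondition is violated (e.g. k > n)."""
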