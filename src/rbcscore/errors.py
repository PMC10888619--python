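"""Exception hierarchy for the rbcscore package."""


class RbcScoreError(Exception):
    """Base class for all package errors."""


class SchemaError(RbcScoreError):
    """A table is structurally incompatible with the cohort schema
    (e.g. a mandatory column is absent)."""


class ValidationError(RbcScoreError):
    """Row- or field-level content violates the schema (out-of-enumeration
    category, non-finite numeric, forbidden missing value, ...)."""

    def __init__(self, message, details=None):
        super().__init__(message)
        #: list of (row, field, problem) tuples where applicable
        self.details = list(details) if details else []


class FitError(RbcScoreError):
    """Logistic model cannot be fitted (single-class outcome,
    rank-deficient design, ...)."""


class SelectionError(RbcScoreError):
    """Resampling selection cannot produce a result."""


class ScoringError(RbcScoreError):
    """Point-system derivation or patient scoring failed."""
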