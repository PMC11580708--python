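"""Exception hierarchy for cohort validation, scoring and ROC statistics."""


class CopdIndicesError(Exception):
    """Base class for all package errors."""


class CohortValidationError(CopdIndicesError, ValueError):
    """A record (or a field of one) violates a type-level invariant."""

    def __init__(self, message: str, field: str | None = None, row: int | None = None):
        self.field = field
        self.row = row
        prefix = f"row {row}: " if row is not None else ""
        super().__init__(prefix + message)


class SchemaError(CopdIndicesError, ValueError):
    """A cohort CSV does not match the documented schema."""


class ScoringError(CopdIndicesError, ValueError):
    """A record cannot be scored (missing or invalid component field)."""


class UndefinedAUCError(CopdIndicesError, ValueError):
    """AUC requested for an outcome vector with a single class."""


class DegenerateVarianceError(CopdIndicesError, ValueError):
    """DeLong variance of the AUC difference is zero while the AUCs differ."""


class CalibrationError(CopdIndicesError, ValueError):
    """Mortality targets are unattainable for the configured coefficients."""


class ConfigError(CopdIndicesError, ValueError):
    """A generator or pipeline configuration value is infeasible."""
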