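"""Patient-level domain records for hospitalized COPD cohorts.

A :class:`PatientRecord` captures one index admission: demographics,
spirometry, dyspnea grade, prior-year severe exacerbations, admission
hemoglobin, and fixed-horizon vital status at one and three years.
Outcomes are binary (not time-to-event): every included patient has at
least three years of follow-up, so no censoring model is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from enum import Enum

from .errors import CohortValidationError

__all__ = [
    "Sex",
    "PatientRecord",
    "PhysiologicalBounds",
    "EligibilityRule",
    "EligibilityReport",
    "WHO_HB_THRESHOLD",
    "classify_anemia",
    "check_eligibility",
]


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


#: WHO hemoglobin thresholds (g/dL); anemia is Hb strictly below the threshold.
WHO_HB_THRESHOLD: dict[Sex, float] = {Sex.FEMALE: 12.0, Sex.MALE: 13.0}


@dataclass(frozen=True)
class PhysiologicalBounds:
    """Admissible (inclusive) ranges for the numeric record fields."""

    age: tuple[float, float] = (18, 110)
    bmi: tuple[float, float] = (10.0, 70.0)
    fev1_pct: tuple[float, float] = (5.0, 150.0)
    hemoglobin: tuple[float, float] = (3.0, 22.0)


DEFAULT_BOUNDS = PhysiologicalBounds()


def classify_anemia(hemoglobin: float, sex: Sex) -> bool:
    """WHO anemia rule: Hb < 12 g/dL for women, Hb < 13 g/dL for men.

    The comparison is strict: a woman with Hb exactly 12.0 is not anemic.
    """
    if not isinstance(sex, Sex):
        raise CohortValidationError(f"invalid sex value {sex!r}", field="sex")
    if not math.isfinite(hemoglobin) or hemoglobin <= 0:
        raise CohortValidationError(
            f"hemoglobin must be positive and finite, got {hemoglobin!r}",
            field="hemoglobin",
        )
    return hemoglobin < WHO_HB_THRESHOLD[sex]


@dataclass(frozen=True)
class PatientRecord:
    """One COPD admission with fixed-horizon survival outcomes.

    Invariants enforced at construction: ``dead_1y`` implies ``dead_3y``
    (death is absorbing), mMRC in {0..4}, counts non-negative, and the
    continuous fields within :data:`DEFAULT_BOUNDS`.
    """

    patient_id: str
    age: int
    sex: Sex
    bmi: float
    fev1_pct: float
    mmrc: int
    severe_exacerbations_prior_year: int
    hemoglobin: float
    dead_1y: bool
    dead_3y: bool
    fev1_fvc_ratio: float | None = None
    pack_years: float | None = None

    def __post_init__(self) -> None:
        validate_record(self)

    @property
    def anemic(self) -> bool:
        return classify_anemia(self.hemoglobin, self.sex)


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not math.isfinite(value):
        raise CohortValidationError(f"{name} must be finite, got {value!r}", field=name)
    if not lo <= value <= hi:
        raise CohortValidationError(
            f"{name}={value!r} outside admissible range [{lo}, {hi}]", field=name
        )


def validate_record(rec: PatientRecord, bounds: PhysiologicalBounds = DEFAULT_BOUNDS) -> None:
    """Raise :class:`CohortValidationError` naming the offending field."""
    if not isinstance(rec.sex, Sex):
        raise CohortValidationError(f"invalid sex value {rec.sex!r}", field="sex")
    if int(rec.age) != rec.age:
        raise CohortValidationError(f"age must be an integer, got {rec.age!r}", field="age")
    _check_range("age", rec.age, *bounds.age)
    _check_range("bmi", rec.bmi, *bounds.bmi)
    _check_range("fev1_pct", rec.fev1_pct, *bounds.fev1_pct)
    _check_range("hemoglobin", rec.hemoglobin, *bounds.hemoglobin)
    if rec.mmrc not in (0, 1, 2, 3, 4):
        raise CohortValidationError(
            f"mmrc must be an integer grade in 0..4, got {rec.mmrc!r}", field="mmrc"
        )
    n_ex = rec.severe_exacerbations_prior_year
    if int(n_ex) != n_ex or n_ex < 0:
        raise CohortValidationError(
            f"severe_exacerbations_prior_year must be a non-negative integer, got {n_ex!r}",
            field="severe_exacerbations_prior_year",
        )
    if rec.fev1_fvc_ratio is not None:
        if not math.isfinite(rec.fev1_fvc_ratio) or rec.fev1_fvc_ratio <= 0:
            raise CohortValidationError(
                f"fev1_fvc_ratio must be positive, got {rec.fev1_fvc_ratio!r}",
                field="fev1_fvc_ratio",
            )
    if rec.pack_years is not None:
        if not math.isfinite(rec.pack_years) or rec.pack_years < 0:
            raise CohortValidationError(
                f"pack_years must be non-negative, got {rec.pack_years!r}",
                field="pack_years",
            )
    if rec.dead_1y and not rec.dead_3y:
        raise CohortValidationError(
            "dead_1y=True with dead_3y=False violates the absorbing-death invariant",
            field="dead_3y",
        )


@dataclass(frozen=True)
class EligibilityRule:
    """Spirometric COPD inclusion criteria for the cohort.

    Defaults: age >= 40 years, smoking history >= 10 pack-years, and
    post-bronchodilator FEV1/FVC < 70%.
    """

    min_age: float = 40.0
    min_pack_years: float = 10.0
    max_fev1_fvc: float = 70.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise CohortValidationError(
                    f"eligibility threshold {f.name} must be positive", field=f.name
                )


@dataclass
class EligibilityReport:
    """Violations are disqualifying; warnings flag unverifiable criteria."""

    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def eligible(self) -> bool:
        return not self.violations


def check_eligibility(
    record: PatientRecord, rule: EligibilityRule = EligibilityRule()
) -> EligibilityReport:
    """Check a record against the inclusion criteria; report, never throw.

    Missing optional fields (pack_years, fev1_fvc_ratio) cannot be verified
    and produce warnings rather than violations.
    """
    report = EligibilityReport()
    if record.age < rule.min_age:
        report.violations.append(
            f"age {record.age} below minimum {rule.min_age:g} years"
        )
    if record.pack_years is None:
        report.warnings.append("pack_years missing: smoking-history criterion not verifiable")
    elif record.pack_years < rule.min_pack_years:
        report.violations.append(
            f"pack_years {record.pack_years:g} below minimum {rule.min_pack_years:g}"
        )
    if record.fev1_fvc_ratio is None:
        report.warnings.append("fev1_fvc_ratio missing: obstruction criterion not verifiable")
    elif record.fev1_fvc_ratio >= rule.max_fev1_fvc:
        report.violations.append(
            f"fev1_fvc_ratio {record.fev1_fvc_ratio:g} not below {rule.max_fev1_fvc:g}%"
        )
    return report
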