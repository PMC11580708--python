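"""Point tables and score computation for the BODEx and ADO indices
and their anemia-augmented variants (BODEx-A3, ADO-A3).

Each index is a sum of small integer point contributions from categorical
bins over one record field.  The bin tables are declarative data (one
place, config-overridable), with the published ranges as consistency
checks: BODEx 0-9, ADO 0-10, and with the default 3-point anemia weight
BODEx-A3 0-12, ADO-A3 0-13.

Bins partition the real line with half-open intervals so that continuous
inputs (BMI, FEV1 %predicted) map to exactly one category:

* BODEx — BMI: >21 -> 0, <=21 -> 1; FEV1%: [65,inf) -> 0, [50,65) -> 1,
  [36,50) -> 2, (0,36) -> 3; mMRC: 0-1 -> 0, 2 -> 1, 3 -> 2, 4 -> 3;
  severe exacerbations (prior year): 0 -> 0, 1-2 -> 1, >=3 -> 2.
* ADO (original 0-10 version) — age: <50 -> 0 then one point per decade up
  to >=90 -> 5; mMRC as above; FEV1%: >=65 -> 0, 36-64 -> 1, <=35 -> 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ScoringError
from .records import PatientRecord, classify_anemia

__all__ = [
    "ScoringTable",
    "IndexDefinition",
    "AugmentationRule",
    "BODEX",
    "ADO",
    "bodex_score",
    "ado_score",
    "augment_score",
    "score_cohort",
]


@dataclass(frozen=True)
class ScoringTable:
    """Point assignment for one index component.

    ``breaks`` are ascending interior breakpoints over the component's
    field; ``points`` has one entry per interval, left to right.  With
    ``right_closed=False`` intervals are ``[b_i, b_{i+1})`` (value equal
    to a breakpoint falls in the interval to its right); with
    ``right_closed=True`` they are ``(b_i, b_{i+1}]``.
    """

    component: str
    field: str
    breaks: tuple[float, ...]
    points: tuple[int, ...]
    right_closed: bool = False

    def __post_init__(self) -> None:
        if len(self.points) != len(self.breaks) + 1:
            raise ScoringError(
                f"{self.component}: need len(breaks)+1 point values, got "
                f"{len(self.points)} for {len(self.breaks)} breaks"
            )
        if any(p < 0 or int(p) != p for p in self.points):
            raise ScoringError(f"{self.component}: points must be non-negative integers")
        if list(self.breaks) != sorted(self.breaks) or len(set(self.breaks)) != len(self.breaks):
            raise ScoringError(f"{self.component}: breaks must be strictly ascending")

    @property
    def max_points(self) -> int:
        return max(self.points)

    @property
    def min_points(self) -> int:
        return min(self.points)

    def points_for(self, values):
        """Vectorized bin lookup; scalar in -> scalar int out."""
        side = "left" if self.right_closed else "right"
        idx = np.searchsorted(np.asarray(self.breaks), values, side=side)
        result = np.asarray(self.points)[idx]
        return int(result) if np.isscalar(values) else result

    def representative_values(self) -> list[float]:
        """One value inside each bin (for exhaustive range enumeration)."""
        reps = []
        for i in range(len(self.points)):
            if self.right_closed:
                reps.append(self.breaks[i] if i < len(self.breaks) else self.breaks[-1] + 1.0)
            else:
                reps.append(self.breaks[i - 1] if i > 0 else self.breaks[0] - 1.0)
        return reps

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "field": self.field,
            "breaks": list(self.breaks),
            "points": list(self.points),
            "right_closed": self.right_closed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringTable":
        return cls(
            component=d["component"],
            field=d["field"],
            breaks=tuple(d["breaks"]),
            points=tuple(d["points"]),
            right_closed=bool(d.get("right_closed", False)),
        )


@dataclass(frozen=True)
class IndexDefinition:
    """A named prognostic index: the sum of its component point tables."""

    name: str
    components: tuple[ScoringTable, ...]

    @property
    def min_score(self) -> int:
        return sum(c.min_points for c in self.components)

    @property
    def max_score(self) -> int:
        return sum(c.max_points for c in self.components)

    @property
    def fields(self) -> tuple[str, ...]:
        return tuple(c.field for c in self.components)

    def score(self, record: PatientRecord) -> int:
        total = 0
        for comp in self.components:
            value = getattr(record, comp.field, None)
            if value is None:
                raise ScoringError(
                    f"{self.name}: record {record.patient_id!r} missing field {comp.field!r}"
                )
            total += comp.points_for(value)
        return total

    def score_values(self, data: Mapping[str, np.ndarray]) -> np.ndarray:
        """Vectorized scoring over field arrays (used by the generator)."""
        parts = [comp.points_for(np.asarray(data[comp.field])) for comp in self.components]
        return np.sum(parts, axis=0)

    def attainable_scores(self) -> set[int]:
        """Every total attainable over the cross-product of all bins."""
        per_component = [set(c.points) for c in self.components]
        return {sum(combo) for combo in product(*per_component)}

    def to_dict(self) -> dict:
        return {"name": self.name, "components": [c.to_dict() for c in self.components]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "IndexDefinition":
        return cls(
            name=d["name"],
            components=tuple(ScoringTable.from_dict(c) for c in d["components"]),
        )


_MMRC_TABLE = dict(field="mmrc", breaks=(2, 3, 4), points=(0, 1, 2, 3))

BODEX = IndexDefinition(
    name="BODEx",
    components=(
        ScoringTable("bmi", "bmi", breaks=(21.0,), points=(1, 0), right_closed=True),
        ScoringTable("fev1", "fev1_pct", breaks=(36.0, 50.0, 65.0), points=(3, 2, 1, 0)),
        ScoringTable("dyspnea", **_MMRC_TABLE),
        ScoringTable(
            "exacerbations", "severe_exacerbations_prior_year", breaks=(1, 3), points=(0, 1, 2)
        ),
    ),
)

ADO = IndexDefinition(
    name="ADO",
    components=(
        ScoringTable("age", "age", breaks=(50, 60, 70, 80, 90), points=(0, 1, 2, 3, 4, 5)),
        ScoringTable("dyspnea", **_MMRC_TABLE),
        ScoringTable("fev1", "fev1_pct", breaks=(36.0, 65.0), points=(2, 1, 0)),
    ),
)

INDEX_FAMILIES: dict[str, IndexDefinition] = {"bodex": BODEX, "ado": ADO}


@dataclass(frozen=True)
class AugmentationRule:
    """Anemia augmentation: add ``anemia_points`` to the base score when the
    patient is anemic.  0 makes the base index a special case; the swept
    range in the source analysis is 1..4 with 3 the adopted default."""

    anemia_points: int = 3

    def __post_init__(self) -> None:
        if self.anemia_points not in (0, 1, 2, 3, 4):
            raise ScoringError(
                f"anemia_points must be an integer in 0..4, got {self.anemia_points!r}"
            )

    @property
    def label_suffix(self) -> str:
        return f"-A{self.anemia_points}"


def bodex_score(record: PatientRecord) -> int:
    """BODEx total (BMI, obstruction, dyspnea, exacerbations), 0-9."""
    return BODEX.score(record)


def ado_score(record: PatientRecord) -> int:
    """ADO total (age, dyspnea, obstruction), original version, 0-10."""
    return ADO.score(record)


def augment_score(base_score: int, anemic: bool, rule: AugmentationRule = AugmentationRule()) -> int:
    """Base score plus the anemia weight if anemic, else unchanged."""
    return base_score + (rule.anemia_points if anemic else 0)


def score_cohort(
    records: Sequence[PatientRecord],
    index: IndexDefinition,
    rule: AugmentationRule | None = None,
) -> pd.DataFrame:
    """Score every record; one row per patient, in input order.

    Columns: patient_id, index, base_score, anemic and, when ``rule`` is
    given, augmented_score.
    """
    rows = []
    for rec in records:
        try:
            base = index.score(rec)
        except ScoringError as err:
            raise ScoringError(f"patient {rec.patient_id!r}: {err}") from err
        anemic = classify_anemia(rec.hemoglobin, rec.sex)
        row = {
            "patient_id": rec.patient_id,
            "index": index.name,
            "base_score": base,
            "anemic": anemic,
        }
        if rule is not None:
            row["augmented_score"] = augment_score(base, anemic, rule)
        rows.append(row)
    columns = ["patient_id", "index", "base_score", "anemic"]
    if rule is not None:
        columns.append("augmented_score")
    return pd.DataFrame(rows, columns=columns)
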