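"""CSV reading and writing for patient cohorts.

Schema (comma-delimited, header row, names case-insensitive)::

    patient_id, age, sex, bmi, fev1_pct, fev1_fvc_ratio, mmrc,
    severe_exacerbations_prior_year, pack_years, hemoglobin, dead_1y, dead_3y

Empty cells denote missing values and are accepted only for the optional
fields ``fev1_fvc_ratio`` and ``pack_years``.  Boolean columns accept
{0, 1, true, false, yes, no}; sex accepts {f, m, female, male}.  Floats are
written with ``repr`` so that a write/read round-trip is the identity.
"""

from __future__ import annotations

import csv
from os import PathLike
from typing import Iterable

from .errors import CohortValidationError, SchemaError
from .records import DEFAULT_BOUNDS, PatientRecord, PhysiologicalBounds, Sex

__all__ = ["COLUMNS", "read_cohort", "write_cohort"]

COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "bmi",
    "fev1_pct",
    "fev1_fvc_ratio",
    "mmrc",
    "severe_exacerbations_prior_year",
    "pack_years",
    "hemoglobin",
    "dead_1y",
    "dead_3y",
)

_OPTIONAL = {"fev1_fvc_ratio", "pack_years"}

_BOOL_TOKENS = {
    "0": False, "1": True,
    "false": False, "true": True,
    "no": False, "yes": True,
}

_SEX_TOKENS = {
    "f": Sex.FEMALE, "female": Sex.FEMALE,
    "m": Sex.MALE, "male": Sex.MALE,
}


def _parse_bool(token: str, name: str, row: int) -> bool:
    try:
        return _BOOL_TOKENS[token.strip().lower()]
    except KeyError:
        raise CohortValidationError(
            f"cannot parse {name}={token!r} as a boolean (expected 0/1/true/false/yes/no)",
            field=name, row=row,
        ) from None


def _parse_sex(token: str, row: int) -> Sex:
    try:
        return _SEX_TOKENS[token.strip().lower()]
    except KeyError:
        raise CohortValidationError(
            f"cannot parse sex={token!r} (expected F/M/female/male)", field="sex", row=row
        ) from None


def _parse_number(token: str, name: str, row: int, kind=float):
    try:
        return kind(token)
    except ValueError:
        raise CohortValidationError(
            f"cannot parse {name}={token!r} as {kind.__name__}", field=name, row=row
        ) from None


def read_cohort(
    path: str | PathLike,
    *,
    delimiter: str = ",",
    bounds: PhysiologicalBounds = DEFAULT_BOUNDS,
) -> list[PatientRecord]:
    """Read and validate a cohort CSV; row numbers (header = row 1) are
    carried into every parse or invariant error."""
    records: list[PatientRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected a header row") from None
        names = [h.strip().lower() for h in header]
        missing = [c for c in COLUMNS if c not in names]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        idx = {c: names.index(c) for c in COLUMNS}
        for rownum, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            cell = {c: row[idx[c]].strip() if idx[c] < len(row) else "" for c in COLUMNS}
            for name, value in cell.items():
                if value == "" and name not in _OPTIONAL:
                    raise CohortValidationError(
                        f"required field {name} is empty", field=name, row=rownum
                    )
            try:
                rec = PatientRecord(
                    patient_id=cell["patient_id"],
                    age=_parse_number(cell["age"], "age", rownum, int),
                    sex=_parse_sex(cell["sex"], rownum),
                    bmi=_parse_number(cell["bmi"], "bmi", rownum),
                    fev1_pct=_parse_number(cell["fev1_pct"], "fev1_pct", rownum),
                    fev1_fvc_ratio=(
                        None if cell["fev1_fvc_ratio"] == ""
                        else _parse_number(cell["fev1_fvc_ratio"], "fev1_fvc_ratio", rownum)
                    ),
                    mmrc=_parse_number(cell["mmrc"], "mmrc", rownum, int),
                    severe_exacerbations_prior_year=_parse_number(
                        cell["severe_exacerbations_prior_year"],
                        "severe_exacerbations_prior_year", rownum, int,
                    ),
                    pack_years=(
                        None if cell["pack_years"] == ""
                        else _parse_number(cell["pack_years"], "pack_years", rownum)
                    ),
                    hemoglobin=_parse_number(cell["hemoglobin"], "hemoglobin", rownum),
                    dead_1y=_parse_bool(cell["dead_1y"], "dead_1y", rownum),
                    dead_3y=_parse_bool(cell["dead_3y"], "dead_3y", rownum),
                )
            except CohortValidationError as err:
                if err.row is None:
                    raise CohortValidationError(str(err), field=err.field, row=rownum) from None
                raise
            records.append(rec)
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, Sex):
        return value.value
    return str(value)


def write_cohort(records: Iterable[PatientRecord], path: str | PathLike) -> None:
    """Write records as CSV; ``read_cohort(write_cohort(x)) == x`` field-for-field."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for rec in records:
            writer.writerow([_fmt(getattr(rec, c)) for c in COLUMNS])
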