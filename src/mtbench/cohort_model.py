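"""Trauma cohort data model: patient records, CSV I/O, outcome, eligibility.

One row per patient: demographics, emergency-room (ER) vital signs and labs,
AIS-coded injury features and transfusion counts, in a fixed registry-style
CSV schema.  The massive-transfusion (MT) outcome is administration of
``>= 10`` units of packed red blood cells (pRBC) between ER arrival and ICU
admission.  Eligibility filtering follows a fixed, reported rule order:
adults, primary admission, survival to ICU, known pRBC count, no hemostatic
agents, and complete-case availability of every variable the configured
scores require.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: pRBC units (ER arrival to ICU admission) at or above which MT is positive.
MT_PRBC_THRESHOLD = 10

#: Exact cohort CSV header, in order.
CSV_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "mechanism",
    "primary_admission",
    "survived_to_icu",
    "heart_rate_er",
    "sbp_er",
    "hemoglobin_er",
    "base_excess_er",
    "lactate_er",
    "inr_er",
    "quick_er",
    "gcs",
    "fast_positive",
    "ct_free_fluid",
    "pelvis_ais",
    "femur_ais",
    "prbc_units_er_to_icu",
    "hemostatic_agents",
    "iss",
]


class SchemaError(ValueError):
    """The CSV header does not match the published cohort schema."""


class RowParseError(ValueError):
    """A cell could not be parsed; carries the line number and column name."""

    def __init__(self, line: int, column: str, message: str):
        self.line = line
        self.column = column
        super().__init__(f"line {line}, column '{column}': {message}")


class RangeViolationError(ValueError):
    """A parsed value lies outside its permitted range (strict mode only)."""

    def __init__(self, line: int, column: str, message: str):
        self.line = line
        self.column = column
        super().__init__(f"line {line}, column '{column}': {message}")


class OutcomeUndefinedError(ValueError):
    """MT outcome requested for a record whose pRBC count is unknown."""


@dataclass
class PatientRecord:
    """One patient's demographics, ER physiology/labs, injuries, transfusions.

    Any field other than ``patient_id`` may be ``None`` (missing); missing
    values serialize as empty CSV cells.  ``base_excess_er`` is base excess
    (BE) in mmol/l; base deficit BD = -BE.  ``pelvis_ais`` / ``femur_ais``
    are abbreviated-injury-scale severities with 0 meaning no injury.
    ``quick_er`` (prothrombin time as percent of normal) and ``iss`` are
    descriptive only; no score reads them.
    """

    patient_id: str
    age: Optional[int] = None
    sex: Optional[str] = None                 # "male" | "female"
    mechanism: Optional[str] = None           # "blunt" | "penetrating"
    primary_admission: Optional[bool] = None
    survived_to_icu: Optional[bool] = None
    heart_rate_er: Optional[float] = None     # bpm
    sbp_er: Optional[float] = None            # mmHg
    hemoglobin_er: Optional[float] = None     # g/dl
    base_excess_er: Optional[float] = None    # mmol/l
    lactate_er: Optional[float] = None        # mmol/l
    inr_er: Optional[float] = None
    quick_er: Optional[float] = None          # percent
    gcs: Optional[int] = None                 # 3..15
    fast_positive: Optional[bool] = None
    ct_free_fluid: Optional[bool] = None
    pelvis_ais: Optional[int] = None          # 0..6
    femur_ais: Optional[int] = None           # 0..6
    prbc_units_er_to_icu: Optional[int] = None
    hemostatic_agents: Optional[bool] = None
    iss: Optional[int] = None                 # 0..75


@dataclass
class FilterReport:
    """Attrition accounting for one eligibility-filter pass.

    ``removed_per_rule`` preserves the fixed rule order; counts always
    satisfy ``input_count - sum(removed) == output_count``.
    """

    input_count: int
    removed_per_rule: list = field(default_factory=list)  # [(rule, count)]
    output_count: int = 0

    def as_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "removed_per_rule": [[r, c] for r, c in self.removed_per_rule],
            "output_count": self.output_count,
        }


# field -> (lo, hi, lo_exclusive); None bound = unbounded
_INT_RANGES = {
    "age": (0, None, False),
    "gcs": (3, 15, False),
    "pelvis_ais": (0, 6, False),
    "femur_ais": (0, 6, False),
    "prbc_units_er_to_icu": (0, None, False),
    "iss": (0, 75, False),
}
_FLOAT_RANGES = {
    "heart_rate_er": (0.0, None, False),
    "sbp_er": (0.0, None, False),
    "hemoglobin_er": (0.0, None, False),
    "base_excess_er": (None, None, False),
    "lactate_er": (0.0, None, False),
    "inr_er": (0.0, None, True),
    "quick_er": (0.0, 150.0, True),
}
_BOOL_FIELDS = {
    "primary_admission",
    "survived_to_icu",
    "fast_positive",
    "ct_free_fluid",
    "hemostatic_agents",
}
_ENUM_FIELDS = {
    "sex": ("male", "female"),
    "mechanism": ("blunt", "penetrating"),
}


def validate_record(record: PatientRecord) -> list:
    """Return a list of ``(field, message)`` range/enum violations.

    Missing (``None``) values are not violations; missingness is handled by
    the eligibility filters.
    """
    problems = []
    for name, (lo, hi, lo_excl) in _INT_RANGES.items():
        v = getattr(record, name)
        if v is None:
            continue
        if (lo is not None and v < lo) or (hi is not None and v > hi):
            problems.append((name, f"value {v} outside [{lo}, {hi}]"))
    for name, (lo, hi, lo_excl) in _FLOAT_RANGES.items():
        v = getattr(record, name)
        if v is None:
            continue
        if lo is not None and (v <= lo if lo_excl else v < lo):
            problems.append((name, f"value {v} below {'(' if lo_excl else '['}{lo}"))
        elif hi is not None and v > hi:
            problems.append((name, f"value {v} above {hi}"))
        elif not math.isfinite(v):
            problems.append((name, f"non-finite value {v}"))
    for name, allowed in _ENUM_FIELDS.items():
        v = getattr(record, name)
        if v is not None and v not in allowed:
            problems.append((name, f"value {v!r} not one of {allowed}"))
    return problems


def _parse_cell(column: str, text: str):
    if text == "":
        return None
    if column == "patient_id":
        return text
    if column in _BOOL_FIELDS:
        if text == "true":
            return True
        if text == "false":
            return False
        raise ValueError(f"expected true/false, got {text!r}")
    if column in _ENUM_FIELDS:
        if text in _ENUM_FIELDS[column]:
            return text
        raise ValueError(f"expected one of {_ENUM_FIELDS[column]}, got {text!r}")
    if column in _INT_RANGES:
        return int(text)
    return float(text)


def _format_cell(column: str, value) -> str:
    if value is None:
        return ""
    if column in _BOOL_FIELDS:
        return "true" if value else "false"
    if column in _INT_RANGES:
        return str(int(value))
    if column in _FLOAT_RANGES:
        return repr(float(value))
    return str(value)


def read_cohort(path, strict: bool = False) -> list:
    """Read a cohort CSV into a list of :class:`PatientRecord`.

    Empty cells become missing values (``None``).  Unparsable cells always
    raise :class:`RowParseError` naming the column and line; with
    ``strict=True`` any range/enum violation additionally raises
    :class:`RangeViolationError`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != CSV_COLUMNS:
            raise SchemaError(
                f"header mismatch in {path}: expected {CSV_COLUMNS}, got {header}"
            )
        records = []
        for line, row in enumerate(reader, start=2):
            if len(row) != len(CSV_COLUMNS):
                raise RowParseError(
                    line, "<row>", f"expected {len(CSV_COLUMNS)} fields, got {len(row)}"
                )
            values = {}
            for column, cell in zip(CSV_COLUMNS, row):
                try:
                    values[column] = _parse_cell(column, cell)
                except ValueError as exc:
                    raise RowParseError(line, column, str(exc)) from None
            if values["patient_id"] is None:
                raise RowParseError(line, "patient_id", "must not be empty")
            record = PatientRecord(**values)
            if strict:
                problems = validate_record(record)
                if problems:
                    col, msg = problems[0]
                    raise RangeViolationError(line, col, msg)
            records.append(record)
    return records


def write_cohort(records: Iterable[PatientRecord], path) -> None:
    """Write records to CSV in the exact published schema.

    ``read_cohort(write_cohort(x)) == x`` including the missingness pattern;
    missing values are empty cells, never numeric sentinels.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            writer.writerow(
                [_format_cell(c, getattr(rec, c)) for c in CSV_COLUMNS]
            )


def derive_mt_outcome(record: PatientRecord) -> bool:
    """True iff the patient received >= 10 pRBC units between ER and ICU."""
    if record.prbc_units_er_to_icu is None:
        raise OutcomeUndefinedError(
            f"patient {record.patient_id}: pRBC count unknown; "
            "filter the cohort before deriving the MT outcome"
        )
    return record.prbc_units_er_to_icu >= MT_PRBC_THRESHOLD


def required_fields(score_ids: Optional[Sequence[str]] = None) -> frozenset:
    """Union of record fields needed to compute the given scores (default all)."""
    from . import scores as _scores  # deferred: scores imports this module

    ids = list(_scores.SCORE_IDS) if score_ids is None else list(score_ids)
    out = set()
    for sid in ids:
        out |= _scores.REQUIRED_FIELDS[sid]
    return frozenset(out)


#: Fixed eligibility-rule order (name, predicate-builder is internal).
ELIGIBILITY_RULE_NAMES = [
    "age",
    "primary_admission",
    "icu_survival",
    "prbc_known",
    "hemostatic_agents",
    "complete_case",
]


def apply_eligibility_filters(
    records: Sequence[PatientRecord],
    score_ids: Optional[Sequence[str]] = None,
):
    """Apply the study's eligibility rules in fixed order.

    Retained records satisfy: age >= 18, primary admission, survived to ICU,
    pRBC count known, no hemostatic agents (fibrinogen concentrate, PCC,
    rFVIIa, antifibrinolytics), and complete-case availability of every field
    any requested score needs.  ``score_ids=None`` uses the union over all
    six scores (global complete case); passing a subset gives per-score
    complete-case filtering.

    Returns ``(retained_records, FilterReport)``; each removed record is
    counted against the first rule it violates.
    """
    needed = required_fields(score_ids)

    rules = [
        ("age", lambda r: r.age is not None and r.age >= 18),
        ("primary_admission", lambda r: bool(r.primary_admission)),
        ("icu_survival", lambda r: bool(r.survived_to_icu)),
        ("prbc_known", lambda r: r.prbc_units_er_to_icu is not None),
        ("hemostatic_agents", lambda r: r.hemostatic_agents is not None
         and not r.hemostatic_agents),
        ("complete_case", lambda r: all(
            getattr(r, f) is not None for f in needed)),
    ]

    removed = {name: 0 for name, _ in rules}
    retained = []
    for rec in records:
        for name, ok in rules:
            if not ok(rec):
                removed[name] += 1
                break
        else:
            retained.append(rec)

    report = FilterReport(
        input_count=len(records),
        removed_per_rule=[(name, removed[name]) for name, _ in rules],
        output_count=len(retained),
    )
    return retained, report


_CONTINUOUS_SUMMARY = [
    ("age", "years"),
    ("iss", "points"),
    ("heart_rate_er", "bpm"),
    ("sbp_er", "mmHg"),
    ("hemoglobin_er", "g/dl"),
    ("base_excess_er", "mmol/l"),
    ("lactate_er", "mmol/l"),
    ("inr_er", "ratio"),
    ("quick_er", "%"),
    ("gcs", "points"),
    ("prbc_units_er_to_icu", "units"),
]


def summarize_cohort(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Descriptive table: mean +/- SD, median (IQR) and valid n per
    continuous variable; count and percent per categorical.

    SD is the sample standard deviation (ddof=1; 0 for a single value).
    """
    if len(records) == 0:
        raise ValueError("summarize_cohort requires at least one record")

    rows = []
    for name, unit in _CONTINUOUS_SUMMARY:
        vals = np.array(
            [getattr(r, name) for r in records if getattr(r, name) is not None],
            dtype=float,
        )
        if vals.size == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append({
            "variable": name,
            "unit": unit,
            "kind": "continuous",
            "mean": float(np.mean(vals)),
            "sd": sd,
            "median": float(np.median(vals)),
            "q25": float(np.percentile(vals, 25)),
            "q75": float(np.percentile(vals, 75)),
            "count": None,
            "percent": None,
            "valid_n": int(vals.size),
        })

    categoricals = [
        ("sex_male", lambda r: r.sex, lambda v: v == "male"),
        ("blunt_trauma", lambda r: r.mechanism, lambda v: v == "blunt"),
        ("fast_positive", lambda r: r.fast_positive, bool),
        ("ct_free_fluid", lambda r: r.ct_free_fluid, bool),
        ("hemostatic_agents", lambda r: r.hemostatic_agents, bool),
        ("massive_transfusion", lambda r: r.prbc_units_er_to_icu,
         lambda v: v >= MT_PRBC_THRESHOLD),
    ]
    for name, get, pred in categoricals:
        present = [get(r) for r in records if get(r) is not None]
        if not present:
            continue
        count = sum(1 for v in present if pred(v))
        rows.append({
            "variable": name,
            "unit": "",
            "kind": "categorical",
            "mean": None, "sd": None, "median": None, "q25": None, "q75": None,
            "count": count,
            "percent": 100.0 * count / len(present),
            "valid_n": len(present),
        })

    return pd.DataFrame(rows)
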