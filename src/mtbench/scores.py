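"""Six massive-transfusion prediction scores as declarative band tables.

Each score is a :class:`ScoreDefinition`: a list of components, each
evaluating one patient variable (or derived flag) against an ordered list of
bands; the first matching band's points apply.  Component points are summed,
except components sharing a ``group`` label, which contribute the group
maximum (the TASH fracture block: an unstable pelvis at 6 points and an
open/dislocated femur at 3 points count once, as their maximum -- the only
reading consistent with the published TASH range of 0 to 28).

Boundary semantics are kept bit-exact to the published comparators, which
differ between scores on the same variable (TASH fires at heart rate > 120
where ABC and PWH fire at >= 120; Larson at > 110).  Base deficit BD > 5
mmol/l is evaluated as base excess < -5 (BD = -BE).

The TASH score maps to an MT probability through the published logistic
transform ``p = 1 / (1 + exp(5.4 - 0.3 * TASH))``, which is exactly 0.5 at
a score of 18.
"""

from __future__ import annotations

import math
import operator
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import pandas as pd

from .cohort_model import PatientRecord, derive_mt_outcome


class ScoreInputError(ValueError):
    """A required record field is missing for a score."""

    def __init__(self, score_id: str, patient_id: str, field: str):
        self.score_id = score_id
        self.field = field
        super().__init__(
            f"score '{score_id}': patient {patient_id!r} is missing "
            f"required field '{field}'"
        )


_OPS = {
    "lt": operator.lt,
    "le": operator.le,
    "gt": operator.gt,
    "ge": operator.ge,
}


@dataclass(frozen=True)
class Band:
    """One condition -> points row; ``op`` is lt/le/gt/ge or 'is' (truthy)."""

    op: str
    threshold: object
    points: int

    def matches(self, value) -> bool:
        if self.op == "is":
            return bool(value)
        return _OPS[self.op](value, self.threshold)


@dataclass(frozen=True)
class ScoreComponent:
    """Ordered bands over one variable; first match wins, else 0 points."""

    variable: str
    bands: tuple
    group: Optional[str] = None


@dataclass(frozen=True)
class ScoreDefinition:
    score_id: str
    components: tuple
    max_score: int
    default_cutoff: float


# variable name -> (record fields it reads, accessor)
_VARIABLES: dict = {
    "male": (("sex",), lambda r: r.sex == "male"),
    "penetrating": (("mechanism",), lambda r: r.mechanism == "penetrating"),
    "free_fluid_ct_or_fast": (
        ("ct_free_fluid", "fast_positive"),
        lambda r: bool(r.ct_free_fluid or r.fast_positive),
    ),
}
for _f in (
    "heart_rate_er", "sbp_er", "hemoglobin_er", "base_excess_er",
    "lactate_er", "inr_er", "gcs", "pelvis_ais", "femur_ais",
    "fast_positive",
):
    _VARIABLES[_f] = ((_f,), (lambda name: lambda r: getattr(r, name))(_f))


def _comp(variable, *bands, group=None):
    return ScoreComponent(variable, tuple(Band(*b) for b in bands), group)


TASH = ScoreDefinition(
    "tash",
    (
        _comp("male", ("is", True, 1)),
        _comp("hemoglobin_er", ("lt", 7.0, 8), ("lt", 9.0, 6), ("lt", 10.0, 4),
              ("lt", 11.0, 3), ("lt", 12.0, 2)),
        _comp("base_excess_er", ("lt", -10.0, 4), ("lt", -6.0, 3), ("lt", -2.0, 1)),
        _comp("sbp_er", ("lt", 100.0, 4), ("lt", 120.0, 1)),
        _comp("heart_rate_er", ("gt", 120.0, 2)),
        _comp("fast_positive", ("is", True, 3)),
        # fracture block: clinically unstable pelvis (AIS >= 5) or
        # open/dislocated femur (AIS >= 3); counted once as the maximum
        _comp("pelvis_ais", ("ge", 5, 6), group="fracture"),
        _comp("femur_ais", ("ge", 3, 3), group="fracture"),
    ),
    max_score=28,
    default_cutoff=8.5,
)

# PWH hemoglobin: published bands are <= 7 -> 10 and 7.1..10 -> 1; the gap
# (7.0, 7.1) is assigned to the more severe band (written as < 7.1 -> 10),
# which keeps the component monotone.
PWH = ScoreDefinition(
    "pwh",
    (
        _comp("heart_rate_er", ("ge", 120.0, 1)),
        _comp("sbp_er", ("le", 90.0, 3)),
        _comp("gcs", ("le", 8, 1)),
        _comp("pelvis_ais", ("ge", 4, 1)),       # displaced pelvic fracture
        _comp("free_fluid_ct_or_fast", ("is", True, 2)),
        _comp("base_excess_er", ("lt", -5.0, 1)),  # base deficit > 5
        _comp("hemoglobin_er", ("lt", 7.1, 10), ("le", 10.0, 1)),
    ),
    max_score=19,
    default_cutoff=2.5,
)

VANDROMME = ScoreDefinition(
    "vandromme",
    (
        _comp("lactate_er", ("ge", 5.0, 1)),
        _comp("heart_rate_er", ("gt", 105.0, 1)),
        _comp("inr_er", ("gt", 1.5, 1)),
        _comp("hemoglobin_er", ("le", 11.0, 1)),
        _comp("sbp_er", ("lt", 110.0, 1)),
    ),
    max_score=5,
    default_cutoff=1.5,
)

ABC = ScoreDefinition(
    "abc",
    (
        _comp("penetrating", ("is", True, 1)),
        _comp("sbp_er", ("le", 90.0, 1)),
        _comp("heart_rate_er", ("ge", 120.0, 1)),
        _comp("fast_positive", ("is", True, 1)),
    ),
    max_score=4,
    default_cutoff=0.5,
)

SCHREIBER = ScoreDefinition(
    "schreiber",
    (
        _comp("hemoglobin_er", ("le", 11.0, 1)),
        _comp("inr_er", ("gt", 1.5, 1)),
        _comp("penetrating", ("is", True, 1)),
    ),
    max_score=3,
    default_cutoff=0.5,
)

LARSON = ScoreDefinition(
    "larson",
    (
        _comp("heart_rate_er", ("gt", 110.0, 1)),
        _comp("sbp_er", ("lt", 110.0, 1)),
        _comp("hemoglobin_er", ("lt", 11.0, 1)),
        _comp("base_excess_er", ("le", -6.0, 1)),
    ),
    max_score=4,
    default_cutoff=1.5,
)

#: Canonical score order (descending published AUC, as in the comparison).
SCORE_DEFINITIONS = {
    d.score_id: d for d in (TASH, PWH, VANDROMME, ABC, SCHREIBER, LARSON)
}
SCORE_IDS = tuple(SCORE_DEFINITIONS)

#: Record fields each score requires (for complete-case filtering).
REQUIRED_FIELDS = {
    sid: frozenset(
        f for comp in d.components for f in _VARIABLES[comp.variable][0]
    )
    for sid, d in SCORE_DEFINITIONS.items()
}


def evaluate_score(definition: ScoreDefinition, record: PatientRecord) -> int:
    """Evaluate one declarative score definition on one record."""
    total = 0
    group_best: dict = {}
    for comp in definition.components:
        fields_needed, accessor = _VARIABLES[comp.variable]
        for f in fields_needed:
            if getattr(record, f) is None:
                raise ScoreInputError(definition.score_id, record.patient_id, f)
        value = accessor(record)
        points = 0
        for band in comp.bands:
            if band.matches(value):
                points = band.points
                break
        if comp.group is None:
            total += points
        else:
            group_best[comp.group] = max(group_best.get(comp.group, 0), points)
    return total + sum(group_best.values())


def tash_score(record: PatientRecord) -> int:
    """Trauma-Associated Severe Hemorrhage score, 0..28 (weighted)."""
    return evaluate_score(TASH, record)


def pwh_score(record: PatientRecord) -> int:
    """Prince of Wales Hospital / Rainer score, 0..19 (weighted)."""
    return evaluate_score(PWH, record)


def vandromme_score(record: PatientRecord) -> int:
    """Vandromme score, 0..5 (unweighted; lactate, HR, INR, Hb, SBP)."""
    return evaluate_score(VANDROMME, record)


def abc_score(record: PatientRecord) -> int:
    """Assessment of Blood Consumption (Nunez) score, 0..4 (non-laboratory)."""
    return evaluate_score(ABC, record)


def schreiber_score(record: PatientRecord) -> int:
    """Schreiber score, 0..3 (military derivation; Hb, INR, mechanism)."""
    return evaluate_score(SCHREIBER, record)


def larson_score(record: PatientRecord) -> int:
    """Larson score, 0..4 (military derivation; HR, SBP, Hb, base excess)."""
    return evaluate_score(LARSON, record)


SCORERS: dict = {
    "tash": tash_score,
    "pwh": pwh_score,
    "vandromme": vandromme_score,
    "abc": abc_score,
    "schreiber": schreiber_score,
    "larson": larson_score,
}


def tash_probability(score: float) -> float:
    """MT probability for a TASH score: ``1 / (1 + exp(5.4 - 0.3 * score))``.

    Strictly increasing; exactly 0.5 at a score of 18.
    """
    return 1.0 / (1.0 + math.exp(5.4 - 0.3 * score))


def score_cohort(
    records: Sequence[PatientRecord],
    score_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Score every record with the requested scores (default: all six).

    Returns a DataFrame with one row per record: ``patient_id``, one integer
    column per score (canonical order), ``tash_probability`` when TASH is
    requested, and the boolean ``mt_outcome``.  Records must already be
    filtered/complete for the requested scores.
    """
    if score_ids is None:
        ids = list(SCORE_IDS)
    else:
        unknown = [s for s in score_ids if s not in SCORE_DEFINITIONS]
        if unknown:
            raise KeyError(f"unknown score id(s): {unknown}")
        ids = [s for s in SCORE_IDS if s in set(score_ids)]

    columns = ["patient_id"] + ids
    if "tash" in ids:
        columns.insert(columns.index("tash") + 1, "tash_probability")
    columns.append("mt_outcome")

    rows = []
    for rec in records:
        row = {"patient_id": rec.patient_id}
        for sid in ids:
            row[sid] = SCORERS[sid](rec)
        if "tash" in ids:
            row["tash_probability"] = tash_probability(row["tash"])
        row["mt_outcome"] = derive_mt_outcome(rec)
        rows.append(row)

    return pd.DataFrame(rows, columns=columns)
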