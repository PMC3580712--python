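"""ROC/AUC validation workflow for the MT prediction scores.

The receiver operating characteristic is built over candidate thresholds at
the midpoints between consecutive distinct observed score values (plus -inf
and +inf sentinels), classifying "positive if score >= threshold".  On
integer scores this convention yields the familiar half-point cut-offs
(e.g. >= 8.5 for TASH).

AUC is the Mann-Whitney concordance probability -- the probability that a
random case outscores a random control, ties counting one half -- which
equals the trapezoidal area under the midpoint ROC exactly.

Confidence intervals: DeLong (default), Hanley-McNeil, or a seeded
stratified percentile bootstrap.  Two AUCs whose symmetric 95% CIs are known
are compared by recovering each standard error as (high - low) / (2 * 1.96)
and referring (AUC1 - AUC2) / sqrt(SE1^2 + SE2^2) to the standard normal --
the CI-derived-SE comparison used when only published intervals are
available.

The "best relationship between sensitivity and specificity" cut-off is the
maximizer of Youden's J = sensitivity + specificity - 1, ties broken toward
the smaller threshold (higher sensitivity: MT screening favors sensitivity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import PatientRecord, derive_mt_outcome
from .scores import SCORE_DEFINITIONS, SCORE_IDS, score_cohort

_Z975 = 1.959964  # two-sided 95% normal quantile, as used in CI<->SE recovery

#: Published per-score cut-offs used by ``cutoff_mode="fixed"``.
FIXED_CUTOFFS = {
    "tash": 8.5,
    "pwh": 2.5,
    "vandromme": 1.5,
    "larson": 1.5,
    "schreiber": 0.5,
    "abc": 0.5,
}


class SingleClassError(ValueError):
    """ROC/AUC undefined: outcomes contain only one class."""


@dataclass
class ROCCurve:
    """Midpoint-threshold ROC: ``positive if score >= threshold``.

    ``thresholds`` ascend from -inf to +inf; sensitivity is non-increasing
    and specificity non-decreasing along them, with endpoints (1, 0) and
    (0, 1).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int


@dataclass
class ClassificationMetrics:
    """Confusion counts and derived metrics at one threshold.

    Metrics with a zero denominator are ``None`` (undefined), never a number.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


def _check_two_class(scores, outcomes):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be equal-length 1-d sequences")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError(
            "ROC/AUC require at least one positive and one negative outcome"
        )
    return s, y, n_pos, n_neg


def roc_curve(scores: Sequence[float], outcomes: Sequence[bool]) -> ROCCurve:
    """Build the midpoint-convention ROC curve."""
    s, y, n_pos, n_neg = _check_two_class(scores, outcomes)
    distinct = np.unique(s)
    mids = (distinct[1:] + distinct[:-1]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    pos = s[y]
    neg = s[~y]
    # positive if score >= threshold; exhaustive confusion counting
    sens = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] < thresholds[:, None]).mean(axis=1)
    return ROCCurve(thresholds, sens, spec, n_pos, n_neg)


def trapezoid_area(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC in (1 - specificity, sensitivity)."""
    x = 1.0 - curve.specificity
    y = curve.sensitivity
    # thresholds ascend => x descends; integrate over ascending x
    return float(np.trapezoid(y[::-1], x[::-1]))


def auc(scores: Sequence[float], outcomes: Sequence[bool]) -> float:
    """Concordance AUC: P(case score > control score) + 0.5 P(tie)."""
    s, y, n_pos, n_neg = _check_two_class(scores, outcomes)
    ranks = stats.rankdata(s)  # midranks handle ties
    rank_sum_pos = ranks[y].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _hanley_mcneil_se(a: float, n_pos: int, n_neg: int) -> float:
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def delong_se(scores: Sequence[float], outcomes: Sequence[bool]) -> float:
    """DeLong standard error of the concordance AUC (midrank placements)."""
    s, y, n_pos, n_neg = _check_two_class(scores, outcomes)
    pos = s[y]
    neg = s[~y]
    ranks_all = stats.rankdata(s)
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    # placement of each case among controls, and vice versa
    v10 = (ranks_all[y] - ranks_pos) / n_neg
    v01 = 1.0 - (ranks_all[~y] - ranks_neg) / n_pos
    s10 = np.var(v10, ddof=1) if n_pos > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n_neg > 1 else 0.0
    return float(np.sqrt(s10 / n_pos + s01 / n_neg))


def auc_confidence_interval(
    scores: Sequence[float],
    outcomes: Sequence[bool],
    method: str = "delong",
    level: float = 0.95,
    n_bootstrap: int = 2000,
    seed: Optional[int] = None,
):
    """Confidence interval for the AUC.

    ``hanley_mcneil`` and ``delong`` are symmetric normal-theory intervals
    clipped to [0, 1]; ``bootstrap`` is a stratified percentile interval
    (resampling cases and controls separately, seeded).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    s, y, n_pos, n_neg = _check_two_class(scores, outcomes)
    a = auc(s, y)
    z = float(stats.norm.ppf(0.5 + level / 2.0))

    if method == "hanley_mcneil":
        se = _hanley_mcneil_se(a, n_pos, n_neg)
    elif method == "delong":
        se = delong_se(s, y)
    elif method == "bootstrap":
        if n_pos < 2 or n_neg < 2:
            raise ValueError("bootstrap CI needs at least 2 cases and 2 controls")
        rng = np.random.default_rng(seed)
        pos = s[y]
        neg = s[~y]
        reps = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            bp = rng.choice(pos, size=n_pos, replace=True)
            bn = rng.choice(neg, size=n_neg, replace=True)
            bs = np.concatenate([bp, bn])
            by = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
            reps[b] = auc(bs, by)
        alpha = 1.0 - level
        lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
        return float(lo), float(hi)
    else:
        raise ValueError(f"unknown CI method {method!r}")

    return float(max(0.0, a - z * se)), float(min(1.0, a + z * se))


def compare_aucs_ci_method(auc1, ci1, auc2, ci2) -> float:
    """Two-sided p-value comparing two AUCs from their symmetric 95% CIs.

    Recovers SE_i = (high_i - low_i) / (2 * 1.959964) and refers
    z = (AUC1 - AUC2) / sqrt(SE1^2 + SE2^2) to the standard normal.
    Intervals must be symmetric about their AUCs (tolerance 1e-6); for
    asymmetric (e.g. clipped) intervals pass standard errors directly to a
    z-test instead.
    """
    for a, (lo, hi) in ((auc1, ci1), (auc2, ci2)):
        if abs((lo + hi) / 2.0 - a) > 1e-6:
            raise ValueError(
                "confidence interval is not symmetric about its AUC; "
                "derive the standard errors directly instead"
            )
    se1 = (ci1[1] - ci1[0]) / (2.0 * _Z975)
    se2 = (ci2[1] - ci2[0]) / (2.0 * _Z975)
    if se1 == 0.0 and se2 == 0.0:
        return 1.0 if auc1 == auc2 else 0.0
    z = (auc1 - auc2) / np.hypot(se1, se2)
    return float(2.0 * stats.norm.sf(abs(z)))


def compare_aucs_z(auc1, ci1, auc2, ci2) -> float:
    """The z statistic underlying :func:`compare_aucs_ci_method`."""
    se1 = (ci1[1] - ci1[0]) / (2.0 * _Z975)
    se2 = (ci2[1] - ci2[0]) / (2.0 * _Z975)
    return float((auc1 - auc2) / np.hypot(se1, se2))


def optimal_cutoff(curve: ROCCurve) -> float:
    """Finite threshold maximizing Youden's J = sens + spec - 1.

    Ties break toward the smaller threshold, i.e. higher sensitivity.
    """
    finite = curve.thresholds[1:-1]
    if finite.size == 0:
        raise ValueError("no finite threshold: scores are all identical")
    j = curve.sensitivity[1:-1] + curve.specificity[1:-1] - 1.0
    return float(finite[int(np.argmax(j))])  # argmax returns first maximum


def classification_metrics(
    scores: Sequence[float],
    outcomes: Sequence[bool],
    threshold: float,
) -> ClassificationMetrics:
    """Confusion counts and Sens/Spec/PPV/NPV at ``score >= threshold``."""
    s, y, _, _ = _check_two_class(scores, outcomes)
    pred = s >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))

    def ratio(num, den):
        return num / den if den > 0 else None

    return ClassificationMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
    )


def performance_table(
    records: Sequence[PatientRecord],
    score_ids: Optional[Sequence[str]] = None,
    cutoff_mode: str = "youden",
    fixed_cutoffs: Optional[dict] = None,
    ci_method: str = "delong",
    level: float = 0.95,
    n_bootstrap: int = 2000,
    seed: Optional[int] = None,
    roc_dir=None,
):
    """Per-score performance summary (AUC, 95% CI, cut-off, Sens/Spec/PPV/NPV).

    ``cutoff_mode="youden"`` selects each score's cut-off on this cohort;
    ``"fixed"`` uses ``fixed_cutoffs`` (defaulting to the published
    half-point cut-offs in :data:`FIXED_CUTOFFS`).  Sens/Spec/PPV/NPV are
    reported as percents.  If ``roc_dir`` is given, per-score ROC
    coordinates are written as ``roc_<score>.csv`` with columns
    threshold, sensitivity, one_minus_specificity.

    Returns ``(summary DataFrame, {score_id: ROCCurve})``.
    """
    if cutoff_mode not in ("youden", "fixed"):
        raise ValueError(f"unknown cutoff_mode {cutoff_mode!r}")
    ids = list(SCORE_IDS) if score_ids is None else list(score_ids)
    unknown = [s for s in ids if s not in SCORE_DEFINITIONS]
    if unknown:
        raise KeyError(f"unknown score id(s): {unknown}")
    cutoffs = dict(FIXED_CUTOFFS)
    if fixed_cutoffs:
        cutoffs.update(fixed_cutoffs)

    matrix = score_cohort(records, ids)
    outcomes = matrix["mt_outcome"].to_numpy(dtype=bool)

    rows = []
    curves = {}
    for sid in ids:
        s = matrix[sid].to_numpy(dtype=float)
        curve = roc_curve(s, outcomes)
        curves[sid] = curve
        a = auc(s, outcomes)
        lo, hi = auc_confidence_interval(
            s, outcomes, method=ci_method, level=level,
            n_bootstrap=n_bootstrap, seed=seed,
        )
        cut = optimal_cutoff(curve) if cutoff_mode == "youden" else cutoffs[sid]
        m = classification_metrics(s, outcomes, cut)

        def pct(v):
            return None if v is None else 100.0 * v

        rows.append({
            "score": sid,
            "auc": a,
            "ci_low": lo,
            "ci_high": hi,
            "cutoff": cut,
            "sensitivity_pct": pct(m.sensitivity),
            "specificity_pct": pct(m.specificity),
            "ppv_pct": pct(m.ppv),
            "npv_pct": pct(m.npv),
            "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
        })

    table = pd.DataFrame(rows)

    if roc_dir is not None:
        roc_dir = Path(roc_dir)
        roc_dir.mkdir(parents=True, exist_ok=True)
        for sid, curve in curves.items():
            pd.DataFrame({
                "threshold": curve.thresholds,
                "sensitivity": curve.sensitivity,
                "one_minus_specificity": 1.0 - curve.specificity,
            }).to_csv(roc_dir / f"roc_{sid}.csv", index=False)

    return table, curves


def performance_table_to_json(table: pd.DataFrame) -> str:
    """Serialize a performance table deterministically (sorted keys)."""
    payload = {
        row["score"]: {
            k: (None if pd.isna(v) else v)
            for k, v in row.items() if k != "score"
        }
        for row in table.to_dict(orient="records")
    }
    return json.dumps(payload, indent=2, sort_keys=True)
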