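"""Synthetic trauma-registry cohort generator.

Emulates the statistical structure the validation pipeline assumes: the
published cohort marginals (age 45.7 +/- 19.3 y, heart rate 89.7 +/- 20
bpm, systolic blood pressure 125.3 +/- 28.6 mmHg, hemoglobin 11.8 +/- 2.6
g/dl, base excess -2.6 +/- 4.3 mmol/l, lactate 3.1 +/- 5.2 mmol/l, Quick
81.2 +/- 21.1 %, ISS 24.3 +/- 13.2; 73.4% male, 95% blunt) and a 5.6% MT
prevalence, with a single latent severity factor ``s ~ N(0, 1)`` inducing
all cross-variable correlation.

Each continuous variable is ``mu + sigma * (rho * s + sqrt(1 - rho^2) *
eps)`` with signed loading ``rho`` (worse physiology at higher severity),
clipped to a physiological range.  Lactate and INR are generated on the log
scale with moments matched to the target mean/SD, since an SD larger than
the mean (lactate 3.1 +/- 5.2) is impossible for a symmetric nonnegative
variable.  Binary injury flags and severe neurological impairment (GCS <=
8) are Bernoulli with a logistic dependence on ``s`` whose intercept is
calibrated by quadrature so the marginal prevalence hits its target.  The
MT outcome is Bernoulli with ``logit P = alpha + beta * s``; ``alpha`` is
found by bisection so the population MT rate equals ``target_prevalence``.
pRBC counts are constructed consistently with the outcome (>= 10 units iff
MT).

Identical spec and seed give a bit-identical cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from .cohort_model import PatientRecord

#: Published cohort marginals (mean, sd); INR is not published and defaults
#: to a realistic lognormal for a mostly-blunt ICU-admitted trauma cohort.
DEFAULT_MARGINALS = {
    "age": (45.7, 19.3),
    "heart_rate_er": (89.7, 20.0),
    "sbp_er": (125.3, 28.6),
    "hemoglobin_er": (11.8, 2.6),
    "base_excess_er": (-2.6, 4.3),
    "lactate_er": (3.1, 5.2),
    "inr_er": (1.2, 0.4),
    "quick_er": (81.2, 21.1),
    "iss": (24.3, 13.2),
}

#: Signed correlation of each variable with latent severity.
DEFAULT_LOADINGS = {
    "heart_rate_er": 0.5,
    "sbp_er": -0.5,
    "hemoglobin_er": -0.5,
    "base_excess_er": -0.5,
    "lactate_er": 0.5,
    "inr_er": 0.5,
    "age": 0.0,
    "quick_er": 0.0,
    "iss": 0.0,
}

#: Severity-linked flag prevalences: displaced/unstable pelvic fracture,
#: open/dislocated femur fracture, FAST-positive, CT free fluid.
DEFAULT_FLAG_PREVALENCES = {
    "pelvis_fracture": 0.10,
    "femur_fracture": 0.06,
    "fast_positive": 0.15,
    "ct_free_fluid": 0.10,
}

#: Variables generated on the log scale (moment-matched lognormal).
_LOG_SCALE = frozenset({"lactate_er", "inr_er"})

#: Physiological clipping ranges applied after generation.
CLIP_RANGES = {
    "age": (18.0, 98.0),
    "heart_rate_er": (0.0, 250.0),
    "sbp_er": (30.0, 300.0),
    "hemoglobin_er": (2.0, 20.0),
    "base_excess_er": (-30.0, 20.0),
    "lactate_er": (0.0, 30.0),
    "inr_er": (0.8, 10.0),
    "quick_er": (5.0, 150.0),
    "iss": (0.0, 75.0),
}

_ROUND_DECIMALS = {
    "heart_rate_er": 1,
    "sbp_er": 1,
    "hemoglobin_er": 2,
    "base_excess_er": 2,
    "lactate_er": 2,
    "inr_er": 2,
    "quick_er": 1,
}

#: Fields hit by inject_missingness: union of what any score reads.
SCORE_RELEVANT_FIELDS = (
    "sex", "mechanism", "heart_rate_er", "sbp_er", "hemoglobin_er",
    "base_excess_er", "lactate_er", "inr_er", "gcs", "fast_positive",
    "ct_free_fluid", "pelvis_ais", "femur_ais",
)

#: Eligibility rules inject_ineligible can violate (one per record).
INELIGIBLE_RULES = (
    "age", "primary_admission", "icu_survival", "prbc_known",
    "hemostatic_agents",
)


class SpecValidationError(ValueError):
    """A CohortSpec field is invalid; the message names the field."""


@dataclass
class CohortSpec:
    """Generator parameters; defaults are the study's published conditions."""

    n: int = 5147
    seed: int = 0
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    male_fraction: float = 0.734
    blunt_fraction: float = 0.95
    severity_loadings: dict = field(
        default_factory=lambda: dict(DEFAULT_LOADINGS))
    flag_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_FLAG_PREVALENCES))
    flag_slope: float = 1.0
    gcs_severe_prevalence: float = 0.20
    gcs_slope: float = 1.0
    outcome_beta: float = 2.0
    target_prevalence: float = 0.056
    missingness_rate: float = 0.0
    ineligible_counts: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not isinstance(self.n, int) or self.n < 1:
            raise SpecValidationError("n: must be a positive integer")
        for name in ("male_fraction", "blunt_fraction",
                     "gcs_severe_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecValidationError(f"{name}: must be in [0, 1]")
        if not 0.0 < self.target_prevalence < 1.0:
            raise SpecValidationError("target_prevalence: must be in (0, 1)")
        if self.outcome_beta < 0.0:
            raise SpecValidationError("outcome_beta: must be >= 0")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise SpecValidationError("missingness_rate: must be in [0, 1)")
        for name, (mean, sd) in self.marginals.items():
            if sd <= 0.0:
                raise SpecValidationError(f"marginals[{name}]: sd must be > 0")
            if name in _LOG_SCALE and mean <= 0.0:
                raise SpecValidationError(
                    f"marginals[{name}]: log-scale mean must be > 0")
        for name, p in self.flag_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise SpecValidationError(
                    f"flag_prevalences[{name}]: must be in [0, 1]")
        for name, c in self.ineligible_counts.items():
            if name not in INELIGIBLE_RULES:
                raise SpecValidationError(
                    f"ineligible_counts[{name}]: unknown rule")
            if c < 0:
                raise SpecValidationError(
                    f"ineligible_counts[{name}]: must be >= 0")


def _expected_prevalence(alpha: float, beta: float) -> float:
    """E[expit(alpha + beta * s)] under s ~ N(0, 1), by Gauss-Hermite."""
    nodes, weights = np.polynomial.hermite.hermgauss(101)
    vals = expit(alpha + beta * np.sqrt(2.0) * nodes)
    return float(np.sum(weights * vals) / np.sqrt(np.pi))


def _calibrate_logit_intercept(
    target: float, slope: float, tolerance: float = 1e-6
) -> float:
    """Bisection on [-20, 20] for E[expit(a + slope*s)] = target."""
    if not 0.0 < target < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")
    if slope == 0.0:
        return float(logit(target))
    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        p = _expected_prevalence(mid, slope)
        if abs(p - target) <= tolerance:
            return mid
        if p < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def calibrate_intercept(spec: CohortSpec, tolerance: float = 1e-4) -> float:
    """Outcome-model intercept alpha with population MT rate = target.

    ``logit P(MT) = alpha + beta * s``; the expectation over the standard
    normal severity is computed by quadrature and inverted by bisection
    (monotone in the target).  ``beta = 0`` reduces to ``logit(target)``.
    """
    if not 0.0 < spec.target_prevalence < 1.0:
        raise ValueError("target_prevalence must be strictly inside (0, 1)")
    if tolerance <= 0.0:
        raise ValueError("tolerance must be > 0")
    return _calibrate_logit_intercept(
        spec.target_prevalence, spec.outcome_beta, tolerance)


def _lognormal_params(mean: float, sd: float):
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


#: Fixed draw order keeps cohorts bit-identical for a given spec + seed.
_CONTINUOUS_ORDER = (
    "age", "heart_rate_er", "sbp_er", "hemoglobin_er", "base_excess_er",
    "lactate_er", "inr_er", "quick_er", "iss",
)

_MILD_GCS_VALUES = np.array([15, 14, 13, 12, 11, 10, 9])
_MILD_GCS_PROBS = np.array([0.55, 0.15, 0.10, 0.06, 0.05, 0.05, 0.04])


def generate_cohort(spec: CohortSpec, return_latent: bool = False):
    """Generate an eligible synthetic cohort per ``spec``.

    All generated patients are adults, primary admissions, survived to ICU,
    with known pRBC counts and no hemostatic agents; missingness and
    ineligible records are added afterwards when ``spec.missingness_rate``
    or ``spec.ineligible_counts`` request them.

    With ``return_latent=True`` also returns the latent severity array
    (before any missingness/ineligible injection).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    s = rng.standard_normal(n)

    columns = {}
    for name in _CONTINUOUS_ORDER:
        mean, sd = spec.marginals[name]
        rho = float(spec.severity_loadings.get(name, 0.0))
        eps = rng.standard_normal(n)
        mix = rho * s + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
        if name in _LOG_SCALE:
            mu, sigma = _lognormal_params(mean, sd)
            x = np.exp(mu + sigma * mix)
        else:
            x = mean + sd * mix
        lo, hi = CLIP_RANGES[name]
        x = np.clip(x, lo, hi)
        if name in _ROUND_DECIMALS:
            x = np.round(x, _ROUND_DECIMALS[name])
        columns[name] = x

    age = columns["age"].astype(int)
    iss = np.round(columns["iss"]).astype(int)

    # GCS: severe (<= 8) with severity-linked probability, else mild draw
    a_gcs = _calibrate_logit_intercept(
        spec.gcs_severe_prevalence, spec.gcs_slope)
    severe = rng.random(n) < expit(a_gcs + spec.gcs_slope * s)
    gcs_severe = rng.integers(3, 9, size=n)
    gcs_mild = rng.choice(_MILD_GCS_VALUES, size=n, p=_MILD_GCS_PROBS)
    gcs = np.where(severe, gcs_severe, gcs_mild)

    # severity-linked injury flags
    flags = {}
    for name in ("pelvis_fracture", "femur_fracture", "fast_positive",
                 "ct_free_fluid"):
        p0 = spec.flag_prevalences[name]
        if p0 <= 0.0:
            flags[name] = np.zeros(n, dtype=bool)
            rng.random(n)  # keep draw order stable across prevalence choices
            continue
        a_flag = _calibrate_logit_intercept(p0, spec.flag_slope)
        flags[name] = rng.random(n) < expit(a_flag + spec.flag_slope * s)

    # AIS severities: displaced (>= 4) pelvis, possibly unstable (>= 5);
    # femur open/dislocated is AIS >= 3
    pelvis_ais = np.where(
        flags["pelvis_fracture"], rng.choice([4, 5], size=n), 0)
    femur_ais = np.where(
        flags["femur_fracture"],
        rng.choice([3, 4, 5], size=n, p=[0.6, 0.3, 0.1]), 0)

    sex = np.where(rng.random(n) < spec.male_fraction, "male", "female")
    mechanism = np.where(
        rng.random(n) < spec.blunt_fraction, "blunt", "penetrating")

    alpha = calibrate_intercept(spec)
    mt = rng.random(n) < expit(alpha + spec.outcome_beta * s)

    # pRBC consistent with the outcome: >= 10 units iff MT
    prbc_mt = 10 + rng.poisson(4.0, size=n)
    prbc_non = np.minimum(rng.poisson(1.2, size=n), 9)
    prbc = np.where(mt, prbc_mt, prbc_non)

    records = []
    for i in range(n):
        records.append(PatientRecord(
            patient_id=f"S{i:06d}",
            age=int(age[i]),
            sex=str(sex[i]),
            mechanism=str(mechanism[i]),
            primary_admission=True,
            survived_to_icu=True,
            heart_rate_er=float(columns["heart_rate_er"][i]),
            sbp_er=float(columns["sbp_er"][i]),
            hemoglobin_er=float(columns["hemoglobin_er"][i]),
            base_excess_er=float(columns["base_excess_er"][i]),
            lactate_er=float(columns["lactate_er"][i]),
            inr_er=float(columns["inr_er"][i]),
            quick_er=float(columns["quick_er"][i]),
            gcs=int(gcs[i]),
            fast_positive=bool(flags["fast_positive"][i]),
            ct_free_fluid=bool(flags["ct_free_fluid"][i]),
            pelvis_ais=int(pelvis_ais[i]),
            femur_ais=int(femur_ais[i]),
            prbc_units_er_to_icu=int(prbc[i]),
            hemostatic_agents=False,
            iss=int(iss[i]),
        ))

    if spec.missingness_rate > 0.0:
        sub_seed = int(rng.integers(2**31))
        records = inject_missingness(records, spec.missingness_rate, sub_seed)
    if any(spec.ineligible_counts.values()):
        sub_seed = int(rng.integers(2**31))
        records = inject_ineligible(records, spec.ineligible_counts, sub_seed)

    if return_latent:
        return records, s
    return records


def inject_missingness(
    records: Sequence[PatientRecord], rate: float, seed: int
):
    """Independently blank each score-relevant field with probability ``rate``.

    Deterministic given ``seed``; returns new records, input untouched.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return [replace(r) for r in records]
    rng = np.random.default_rng(seed)
    mask = rng.random((len(records), len(SCORE_RELEVANT_FIELDS))) < rate
    out = []
    for i, rec in enumerate(records):
        updates = {
            f: None
            for j, f in enumerate(SCORE_RELEVANT_FIELDS) if mask[i, j]
        }
        out.append(replace(rec, **updates) if updates else replace(rec))
    return out


def _ineligible_record(rule: str, index: int, rng) -> PatientRecord:
    rec = PatientRecord(
        patient_id=f"INELIG_{rule}_{index:04d}",
        age=int(rng.integers(25, 70)),
        sex="male",
        mechanism="blunt",
        primary_admission=True,
        survived_to_icu=True,
        heart_rate_er=85.0,
        sbp_er=125.0,
        hemoglobin_er=12.5,
        base_excess_er=-1.0,
        lactate_er=1.5,
        inr_er=1.1,
        quick_er=90.0,
        gcs=15,
        fast_positive=False,
        ct_free_fluid=False,
        pelvis_ais=0,
        femur_ais=0,
        prbc_units_er_to_icu=0,
        hemostatic_agents=False,
        iss=9,
    )
    if rule == "age":
        rec.age = int(rng.integers(16, 18))
    elif rule == "primary_admission":
        rec.primary_admission = False
    elif rule == "icu_survival":
        rec.survived_to_icu = False
    elif rule == "prbc_known":
        rec.prbc_units_er_to_icu = None
    elif rule == "hemostatic_agents":
        rec.hemostatic_agents = True
    else:
        raise ValueError(f"unknown ineligibility rule {rule!r}")
    return rec


def inject_ineligible(
    records: Sequence[PatientRecord], counts: dict, seed: int
):
    """Append records each violating exactly one eligibility rule.

    ``counts`` maps rule names (subset of :data:`INELIGIBLE_RULES`) to the
    number of violating records to append; an eligibility-filter pass on the
    result recovers exactly these removal counts.
    """
    rng = np.random.default_rng(seed)
    out = [replace(r) for r in records]
    for rule in INELIGIBLE_RULES:
        for i in range(int(counts.get(rule, 0))):
            out.append(_ineligible_record(rule, i, rng))
    return out
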