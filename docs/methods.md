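# Methods

This note documents the models and numerical choices behind `mtbench`: the
score tables, the ROC/AUC validation workflow, and the synthetic cohort
generator, along with what the synthetic results do and do not demonstrate.

## Score implementation

Each score is declared as a list of components; a component reads one
patient variable (or a derived flag such as "CT- or FAST-positive for free
fluid") and holds an ordered list of comparator bands. Evaluation is
first-match: at most one band per component contributes, so within-band
perturbations never change the score. Component points are summed, except
components sharing a group label, which contribute the group maximum.

The only grouped block is the TASH fracture block: an unstable pelvic
fracture (AIS ≥ 5, 6 points) and an open/dislocated femur fracture
(AIS ≥ 3, 3 points) count once, as their maximum. Summing them would make
the attainable maximum 31, contradicting the score's defined 0–28 range;
the max-aggregation is the only reading consistent with that range, and the
band-enumeration tests verify 28 is attained.

Boundary semantics are deliberately *not* harmonized across scores, because
the source definitions differ: TASH fires at HR > 120 where ABC and PWH
fire at HR ≥ 120 and Larson at HR > 110; PWH uses SBP ≤ 90 where TASH uses
SBP < 100 / < 120. Base deficit criteria are evaluated on base excess
(BD = −BE): PWH's "BD > 5 mmol/l" is BE < −5; Larson's band is BE ≤ −6 as
defined. Fracture criteria are operationalized on registry-style AIS
severities: "displaced pelvic fracture" (PWH) as pelvis AIS ≥ 4,
"clinically unstable" (TASH) as pelvis AIS ≥ 5.

Two defects in the source definitions are handled explicitly:

- **PWH hemoglobin gap.** The published bands are "≤ 7 → 10" and
  "7.1–10 → 1", leaving (7.0, 7.1) unassigned. We assign the gap to the
  severe band (implemented as Hb < 7.1 → 10), which preserves monotonicity;
  the bands were clearly meant to partition the axis.
- **TASH probability anchor points.** The prose anchor "score ≥ 16 ⇒
  p > 50%" is inconsistent with the score's own logistic transform, under
  which p(16) ≈ 0.354 and p = 0.5 exactly at 18. We implement the printed
  formula and do not guess alternative coefficients.

`quick_er` (Quick value, prothrombin time as percent of normal) is carried
for descriptive output only; scores that need coagulation read INR
directly, and no Quick↔INR conversion is attempted.

## Eligibility filtering

Rules apply in a fixed order so attrition is deterministic and reportable:
age ≥ 18 → primary admission → survived to ICU → pRBC count known → no
hemostatic agents (fibrinogen concentrate, PCC, rFVIIa, antifibrinolytics)
→ complete case. A removed record is charged to the first rule it violates.
Complete-case is global by default — the union of variables needed by all
six scores, so every score is validated on the same patients — with
per-score complete-case available by passing a score subset. Missing values
are empty CSV cells; no numeric sentinels exist anywhere in the format.

## ROC / AUC workflow

- **Thresholds.** Candidate cut-offs are the midpoints between consecutive
  distinct observed score values, plus ∓∞ sentinels; classification is
  "positive if score ≥ threshold". On integer scores this yields half-point
  cut-offs (≥ 8.5 etc.), matching how such cut-offs are conventionally
  reported.
- **AUC.** Mann–Whitney concordance computed from midranks; ties between a
  case and a control count one half. This equals the trapezoidal area under
  the midpoint ROC exactly (a tested invariant at 1e−12, including
  all-tied degenerate inputs, where the curve collapses to the sentinels
  and AUC = 0.5).
- **Confidence intervals.** DeLong (default; midrank placement variance),
  Hanley–McNeil (closed form from AUC and class sizes), or a stratified
  percentile bootstrap (cases and controls resampled separately, seeded).
  Normal-theory intervals are clipped to [0, 1]; clipping can make an
  interval asymmetric.
- **Comparing AUCs from published rows.** When only AUCs and symmetric 95%
  CIs are available, each SE is recovered as (high − low)/(2·1.959964) and
  z = (AUC₁ − AUC₂)/√(SE₁² + SE₂²) is referred to the standard normal. A
  standard-normal reference rather than a finite-df t is used deliberately:
  the df are unknowable from a published CI and the difference is
  negligible at registry scale. Asymmetric intervals are rejected with
  instructions to pass SEs directly, rather than silently mis-recovered.
- **Cut-off selection.** "Best relationship between sensitivity and
  specificity" is operationalized as Youden's J = sens + spec − 1,
  maximized over finite thresholds; ties break toward the smaller
  threshold, i.e. toward sensitivity, because missing an MT patient is the
  costly error in this screening setting.
- **Metrics.** Sens/Spec/PPV/NPV come from exhaustive confusion counting;
  a zero denominator yields an undefined marker (None/empty), never a
  number.

No multiplicity correction is applied across pairwise AUC comparisons; the
workflow performs single highlighted comparisons.

## Synthetic cohort model

One latent severity factor `s ~ N(0, 1)` per patient induces all
cross-variable dependence. Only marginal moments of real registry cohorts
are typically published, so the dependence structure is an explicit
modeling choice, configurable through signed loadings.

- **Continuous variables.** `x = μ + σ(ρ·s + √(1−ρ²)·ε)`, `ε ~ N(0,1)`,
  with default loadings ±0.5 signed so physiology worsens with severity
  (HR, lactate, INR up; SBP, Hb, BE down); age, Quick and ISS load 0 by
  default. Defaults: age 45.7 ± 19.3 y, HR 89.7 ± 20 bpm, SBP 125.3 ± 28.6
  mmHg, Hb 11.8 ± 2.6 g/dl, BE −2.6 ± 4.3 mmol/l, lactate 3.1 ± 5.2
  mmol/l, Quick 81.2 ± 21.1 %, ISS 24.3 ± 13.2. INR has no published
  marginal; the package default is a lognormal moment-matched to
  1.2 ± 0.4, realistic for a mostly-blunt ICU-admitted cohort.
- **Log-scale variables.** Lactate and INR use a moment-matched lognormal
  (an SD exceeding the mean, as for lactate, is impossible for a symmetric
  nonnegative variable). Values are clipped to physiological ranges
  (HR [0, 250], SBP [30, 300], Hb [2, 20], BE [−30, 20], lactate [0, 30],
  INR [0.8, 10], age [18, 98], Quick [5, 150], ISS [0, 75]).
  *Known consequence:* clipping the heavy lactate tail at 30 mmol/l
  removes ≈ 18% of its SD; the lactate mean is essentially unbiased
  (≈ −0.09 mmol/l) but its SD is not expected to match the nominal 5.2.
  Age clipped at 18 (adults only) gains ≈ +0.6 y over the nominal mean;
  both effects sit inside the 4·σ/√n recovery bands tested at n = 5000.
- **GCS and flags.** Severe neurological impairment (GCS ≤ 8) and the four
  injury flags (displaced pelvic fracture 0.10, open/dislocated femur
  0.06, FAST+ 0.15, CT free fluid 0.10 — defaults are generator
  parameters, not registry claims) are Bernoulli with logistic dependence
  on `s` (slope 1.0); each intercept is calibrated by Gauss–Hermite
  quadrature + bisection so the marginal prevalence hits its target.
  Fracture flags map to AIS: pelvis 4 or 5 (equiprobable), femur 3/4/5
  with probabilities 0.6/0.3/0.1.
- **Mechanism and sex.** Penetrating with probability 1 − blunt_fraction
  (default 0.05), independent of severity by default (no joint information
  is published); male with probability 0.734.
- **Outcome.** MT ~ Bernoulli(expit(α + β·s)), β = 2.0 by default;
  α solves E[expit(α + β·s)] = target prevalence (default 0.056) by
  bisection on [−20, 20] with 101-node Gauss–Hermite quadrature
  (tolerance 1e−4 at the public entry point). pRBC counts are constructed
  consistently with the drawn outcome: 10 + Poisson(4) if MT, else
  Poisson(1.2) truncated to {0..9}, so the derived outcome always equals
  the generator's flag.
- **Determinism.** One `numpy` Generator seeded from the spec; all draws
  happen in a fixed order, so identical spec + seed gives bit-identical
  CSV output. Missingness injection (independent per score-relevant field)
  and ineligible-record injection (each appended record violates exactly
  one named rule) consume sub-seeds drawn from the same stream.

**What passing tests show — and don't.** Marginal-mean recovery, calibrated
prevalence, and the ordering "weighted multi-variable scores (TASH, PWH)
beat sparse unweighted ones (ABC)" are properties of this single-factor
model, in which every score input reflects the same latent severity that
drives the outcome. Real registry data have richer structure — multi-site
heterogeneity, skewed marginals beyond mean/SD (published medians imply
skew the generator only captures for the log-scale variables), informative
missingness, ISS↔AIS consistency, mechanism–severity dependence — none of
which the generator models. Absolute synthetic AUCs (≈ 0.68–0.80 at the
defaults) are therefore not estimates of any score's registry performance;
only the pipeline's correctness and the qualitative weighted-vs-unweighted
contrast carry over.

## Problem sizes and tolerances

Marginal recovery is tested at n = 5000 (tolerance 4·σ/√n per mean, 10% on
SDs of normal-scale variables), prevalence calibration at n = 20 000
(±0.6 percentage points around 5.6%), oracle equivalence on 1000 random
small instances (n ≤ 30, integer scores to force ties, 1e−12), and
end-to-end CLI determinism at n = 2000. The acceptance script regenerates
cohorts of 5000 and 20 000 from its `--seed`.

## Limitations

- The declarative engine supports threshold/interval bands and boolean
  flags, which covers these six scores; it is not a general rule language.
- Published AUC CIs from other software may use estimators other than the
  three provided; exact reproduction of third-party intervals is out of
  scope, which is why the CI-derived-SE comparison takes published rows as
  inputs rather than recomputing them.
- No Quick↔INR conversion; cohorts recorded with only one coagulation
  measure cannot have the other imputed.
- The generator makes no attempt at inter-hospital structure, temporal
  trends, or full quantile matching.
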