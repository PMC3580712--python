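# mtbench

A validation bench for clinical scores that predict **massive transfusion
(MT)** — administration of ≥ 10 units of packed red blood cells (pRBC)
between emergency-room arrival and ICU admission — in severely injured
trauma patients.

Early identification of patients who will exsanguinate without aggressive
hemostatic resuscitation is a core triage problem in trauma care. Several
bedside scores have been proposed for it; `mtbench` implements six of the
most widely used — the weighted **TASH** (Trauma-Associated Severe
Hemorrhage, 0–28 points) and **PWH/Rainer** (Prince of Wales Hospital,
0–19) scores, and the unweighted **Vandromme** (0–5), **ABC**
(Assessment of Blood Consumption, 0–4), **Schreiber** (0–3) and **Larson**
(0–4) scores — together with the statistical workflow used to compare them
on a single cohort, and a synthetic trauma-registry generator so the whole
pipeline runs and is testable without access to any registry.

It is aimed at biostatisticians and trauma-registry researchers who want
reproducible, declaratively specified score implementations and a
transparent ROC validation harness.

## What it computes

**Scores as data.** Each score is a table of banded components (variable,
ordered comparator bands, points) evaluated by one generic engine, so band
semantics are bit-exact and mechanically enumerable: e.g. TASH gives 8
points for Hb < 7 g/dl, 4 for SBP < 100 mmHg, 2 for HR > 120/min, and
counts its pelvis/femur fracture block once, as the maximum. The TASH score
x maps to an MT probability via the logistic transform

    p(x) = 1 / (1 + exp(5.4 − 0.3·x)),

which equals 0.5 exactly at x = 18.

**Validation workflow.** With MT as the state variable: ROC curves over
midpoint thresholds ("positive if score ≥ t", giving the familiar
half-point cut-offs on integer scores), AUC as the Mann–Whitney concordance
P(case > control) + ½·P(tie) (identical to the trapezoidal ROC area),
DeLong / Hanley–McNeil / bootstrap 95% CIs, the Youden-J optimal cut-off
(J = sens + spec − 1, ties toward higher sensitivity), Sens/Spec/PPV/NPV
with confusion counts, and the CI-derived-SE comparison of two AUCs:
SE = (CI_high − CI_low)/(2·1.96), z = ΔAUC/√(SE₁² + SE₂²).

**Synthetic cohorts.** A single latent severity factor s ~ N(0,1) couples
physiology (HR, SBP, Hb, BE, lactate, INR, GCS), injury flags and the MT
outcome (logit P = α + β·s, with α calibrated by quadrature + bisection to
a target prevalence, default 5.6%). Marginals default to registry-style
values (e.g. Hb 11.8 ± 2.6 g/dl, SBP 125.3 ± 28.6 mmHg); lactate and INR
are generated on the log scale. See `docs/methods.md` for the model.

## Worked example

```bash
mtbench run --n 20000 --seed 7 --out demo --cutoff-mode youden
```

generates a 20 000-patient synthetic cohort, filters it through the
eligibility rules (adults, primary admission, survived to ICU, pRBC count
known, no hemostatic agents, complete case), scores it and writes
`performance.csv`:

```
    score   auc  ci_low  ci_high  cutoff  sensitivity_pct  specificity_pct  ppv_pct  npv_pct
     tash 0.797   0.784    0.810     6.5           78.686           65.577   12.001   98.098
      pwh 0.786   0.773    0.799     2.5           68.650           74.436   13.809   97.549
vandromme 0.779   0.766    0.793     1.5           76.821           66.917   12.168   97.975
      abc 0.684   0.669    0.700     0.5           61.456           71.522   11.406   96.885
schreiber 0.704   0.689    0.719     0.5           79.751           52.347    9.078   97.744
   larson 0.768   0.754    0.782     1.5           69.361           73.599   13.550   97.577
```

Each row is one score applied to the same cohort: its AUC with DeLong 95%
CI, the Youden-optimal cut-off on this cohort ("positive if score ≥
cut-off"), and the resulting sensitivity, specificity and predictive
values in percent. On synthetic cohorts, as on registry data, the weighted
multi-variable scores (TASH, PWH) capture more of the underlying severity
than the simple unweighted ones (ABC): here TASH leads with AUC 0.797 and
ABC trails at 0.684. The low PPV / high NPV pattern reflects the ~5.6% MT
prevalence. The output directory also contains the cohort CSV, a
descriptive summary table, the per-score matrix, per-score ROC coordinate
files (`roc_<score>.csv`) and the attrition report; reruns with the same
configuration are byte-identical.

The same machinery is importable directly:

```python
from mtbench import CohortSpec, generate_cohort, performance_table
cohort = generate_cohort(CohortSpec(n=5000, seed=42))
table, curves = performance_table(cohort, cutoff_mode="fixed")
```

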