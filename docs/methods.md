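# Methods

## Indices and point tables

BODEx and ADO are sums of integer points over categorical bins of patient
fields. The tables are declarative data (`copd_indices.scoring`), and
every total is checked attainable by brute-force enumeration:

| Component | Bins → points |
|---|---|
| BODEx: BMI (kg/m²) | > 21 → 0; ≤ 21 → 1 |
| BODEx: FEV1 (% predicted) | ≥ 65 → 0; 50–64 → 1; 36–49 → 2; < 36 → 3 |
| BODEx/ADO: mMRC dyspnea | 0–1 → 0; 2 → 1; 3 → 2; 4 → 3 |
| BODEx: severe exacerbations (prior year) | 0 → 0; 1–2 → 1; ≥ 3 → 2 |
| ADO: age (years) | < 50 → 0, then one point per decade, ≥ 90 → 5 |
| ADO: FEV1 (% predicted) | ≥ 65 → 0; 36–64 → 1; ≤ 35 → 2 |

Continuous inputs are mapped with half-open intervals — FEV1 bins are
`[65,∞) [50,65) [36,50) (0,36)` and the BMI threshold is upper-inclusive
(`≤ 21` scores the point) — so the bins partition the real line exactly.
The anemia augmentation adds a configurable weight (default 3, the
adopted value; 0 makes the base index a special case, which simplifies
the weight sweep) to the base score of patients with WHO-defined anemia:
hemoglobin strictly below 12 g/dL (women) or 13 g/dL (men). mMRC is the
0–4 modified scale; no mapping from the 1–5 MRC variant is attempted.
Records missing a scoring field are rejected, never imputed.

## ROC analysis

Orientation is fixed (higher score = higher risk; positive class = dead)
rather than auto-detected, so a pathological cohort can never silently
flip a curve. Candidate cutpoints are the observed unique score values;
the rule at cutpoint c is "score ≥ c". The AUC is the Mann–Whitney
statistic with ties credited ½, computed from midranks; it equals the
trapezoidal area under the empirical ROC curve exactly, and the test
suite verifies both equalities (trapezoid to 1e−12, pair count exactly)
on 1,000 random instances.

The Youden-optimal cutpoint maximizes J = sensitivity + specificity − 1.
Ties on J are broken toward the lowest threshold, i.e. the most sensitive
rule, appropriate for prognostic screening; the comparison uses integer
arithmetic (J scaled by n_pos·n_neg) so exact rational ties cannot be
masked by float rounding.

DeLong's test for two AUCs measured on the same patients uses placement
values: V10ᵢ is the fraction of negatives that positive i outscores (ties
½), V01ⱼ symmetrically. With S₁₀ and S₀₁ the empirical 2×2 covariance
matrices of the paired placements (unbiased divisors m−1, n−1),

    var(Δ) = (S₁₀,aa + S₁₀,bb − 2 S₁₀,ab)/m + (S₀₁,aa + S₀₁,bb − 2 S₀₁,ab)/n,

z = Δ/√var, two-sided normal p, no continuity correction. Identical
curves (var = 0, Δ = 0) are defined as z = 0, p = 1; var = 0 with
differing AUCs raises a degenerate-variance error. A 95% normal CI from
the single-curve DeLong variance is exposed as plumbing. The
implementation is cross-checked in tests against hand-computed 2×2
placements, R pROC's `roc.test` on a frozen fixture (agreement to 1e−9),
a 10,000-draw sign-flip permutation oracle at n = 20, and a 200-cohort
null simulation (type-I error within [0.02, 0.09] at α = 0.05).

## Synthetic cohort generator

The generator emulates the baseline structure of a single-center cohort
of 141 admissions: 26/141 female, age 73 ± 10 y (truncated to 40–100),
BMI 27 ± 6 kg/m² (13–55), FEV1 46 ± 17 % predicted (10–120), mMRC drawn
N(2.2, 0.9) rounded and clipped to 0–4, pack-years 59 ± 27 (≥ 10),
anemia prevalence 24%, and severe exacerbation counts from a zero-inflated
model (P(0) = 0.49, else 1 + Poisson(λ) with λ fixed by the overall mean
1.3; the marginal SD 1.7 is approximate, not separately calibrated).
Covariates are drawn independently except:

- **Hemoglobin** is conditioned on anemia status and sex, from truncated
  normals on the correct side of the WHO threshold (anemic women
  N(10.8, 0.8) < 12; anemic men N(11.5, 1.0) < 13; non-anemic
  N(14.2, 1.2) / N(15.0, 1.3) above the threshold). These strata are the
  package's own choice, configurable.
- **FEV1/FVC** is drawn N(55, 8) truncated below 70% so every record
  satisfies the spirometric inclusion criterion; it is carried for
  eligibility checking only and is not scored.
- **Mortality** follows a logistic mechanism
  `P(dead by horizon h) = expit(α_h + β_index·S + β_anemia·A)` with S the
  patient's base BODEx score and A the anemia indicator. The intercepts
  α_1y, α_3y are found by bisection (scipy) on a 100,000-draw covariate
  sample from a dedicated fixed stream, to 1e−4 on the expected
  proportion, so the expected mortality equals the 15% / 34% targets;
  they are cached because they do not depend on the cohort seed. With
  both β = 0 the closed form logit(target) is used. One-year deaths are
  sampled as a subset of three-year deaths via the conditional
  probability p_1y/p_3y (clipped to [0,1]), so death is absorbing by
  construction.

Defaults β_index = 0.50, β_anemia = 1.50 log-odds were fixed once by
calibrating the simulated three-year discrimination to the reported
range for cohorts of this type (base AUC ≈ 0.68, augmented ≈ 0.75 on
average), under the constraint β_anemia/β_index = 3 so that anemia is
worth exactly the adopted 3 index points on the log-odds scale. A single
logistic mechanism with one coefficient pair cannot make one-year
discrimination exceed three-year discrimination; the three-year horizon
(the statistically decisive one) was prioritized.

Randomness: one `SeedSequence` per cohort, spawned into named per-field
substreams in a fixed, append-only order, so adding a field never
perturbs earlier fields and a fixed seed yields bit-identical cohorts.

**What passing tests show — and don't.** The generator matches marginal
moments and prevalences, not the joint dependence of real admission data
(e.g. FEV1, dyspnea and exacerbation history are correlated in patients
but independent here, and anemia is independent of the other covariates).
Pipeline properties verified on these cohorts (effect recovery, test
calibration, determinism) therefore validate the machinery, not the
clinical performance of the indices on any real population; the printed
AUCs of the source cohort are not reproducible without its (undeposited)
patient data.

A note on the negative control: with β_anemia = 0 the anemia augmentation
adds points uncorrelated with outcome, which on average *lowers* the AUC
(adding noise to an informative score is strictly harmful in
expectation). The control therefore checks that no positive gain remains
and that the mean difference is ≤ 0, not that the difference is centered
on zero.

## Analysis pipeline

`run_analysis` is a pure function of the cohort and the configuration:
8 index × horizon cells (AUC + Youden operating point), 4 within-family
DeLong comparisons (significance at α = 0.05), the anemia-weight sweep
(weights 1–4 × 2 families × 2 horizons = 16 AUCs, argmax marked, ties
marked jointly), and — flagged as an appendix beyond the source tables —
cross-family comparisons of the base indices. A horizon with a single
outcome class is reported as a horizon-level error while the other
horizon is still evaluated. Which horizon or aggregate should define the
"best" sweep weight is deliberately not hard-coded; the sweep reports all
cells. ROC coordinates are exportable as CSV for redrawing curves;
figure styling is out of scope.

## Problem sizes in the checked properties

Acceptance-style checks use 1,000 random ROC instances (n ≤ 30), 200
null cohorts and 200 effect-recovery replicates at n = 141, and 50
replicate cohorts for generator calibration (tolerance ±2 percentage
points on prevalence and mortality); calibration itself uses 100,000
draws. These sizes keep the full suite fast while leaving Monte-Carlo
error well inside the asserted bands.

## Known limitations

- Fixed-horizon binary outcomes only; no censoring, competing risks or
  time-dependent ROC.
- Sex is binary, per the modeled cohort description.
- The original BODE (six-minute walk distance) and the updated 15-point
  ADO are out of scope.
- Exacerbation counts are taken as supplied in the single record field;
  whether emergency-department visits count toward "severe" events is an
  upstream aggregation decision.
- The ADO age binning follows the original 0–10 formulation; the tables
  are data, so a corrected source table changes configuration, not code.
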