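# Methods

## Age estimation and classing

Each calibration is a fixed linear map `age = intercept + slope × hoof`
(days; mm).  We do not refit these regressions; coefficients are bundled
in `src/fawnfate/data/age_models.tsv` and users may register additional
models at runtime.  Negative predictions are truncated to zero before any
survival use: a captured animal cannot predate its own birth.  Estimated
age `a` maps to the integer day class `floor(a)` — class `d` means the
animal is `d·24` to `(d+1)·24` hours old, so class 0 is a newborn and
enters the first survival interval, class 1 the second, and so on.
Accuracy against known-age animals is scored on these integer classes
(known newborns are only resolved to ≤24 h, so finer comparison would be
spurious): the proportion within tolerance `t` is the fraction with
`|estimated class − true class| ≤ t`.

Sample summaries of age estimates use the *raw* (untruncated) ages, since
a calibration with a strongly negative intercept legitimately has a
negative mean over newborns; SE is the `n−1` sample standard deviation
over `√n`, with SE 0 for a single animal by convention, and table
rounding is half-away-from-zero to one decimal.

## Cohort simulator

The simulator emulates the field design that generated the original data:
a birth pulse (births uniform over a 3-week window), capture at a
configurable age (default: all at age 0, because the field protocol
discards captures older than ~24 h), per-site hoof growth at birth drawn
from a normal truncated at 0 mm, and linear hoof growth (0.32 mm/day,
the reciprocal of a typical calibration slope) for animals captured
later.

* **Site structure.** Default site means and weights are the published
  white-tailed deer site summaries (2.70 mm n=17, 1.98 mm n=6, 1.92 mm
  n=12, 1.98 mm n=36); mule deer and pronghorn year means are likewise
  bundled in `fawnfate.study`.  The default within-site SD of 0.35 mm was
  back-derived once from the published site 95% CIs (implied SDs 0.18–0.57
  mm) and is not tuned.
* **Hazard.** Daily death probability is piecewise constant, elevated on
  days 1–14 when neonatal mortality concentrates.  Presets are calibrated
  to the published 30-day survival point estimates: white-tailed deer
  0.012/0.003 (true S₃₀ = 0.805 ≈ 0.80), mule deer 0.040/0.015 (0.443 ≈
  0.43).  No pronghorn survival was published; its preset 0.030/0.010
  (S₃₀ ≈ 0.56) was chosen once as a realistic intermediate.
* **Competing events.** Death and collar shedding are competing daily
  Bernoulli events; within a day death is evaluated first (documented,
  arbitrary).  Shedding is independent of fate, matching the assumption
  that justifies right-censoring.
* **Monitoring.** Relocation is daily through day 30 and weekly
  thereafter (with a final check at the horizon).  Deaths are recorded at
  the exact day in the daily phase and at the floored midpoint between
  the last relocation alive and the detection day in the weekly phase.
  Shed collars are recorded with the *raw* retrieval day plus the
  last-alive day; the encounter builder applies the censoring rule so the
  midpoint is never applied twice.
* **Reproducibility.** One `numpy` Generator per cohort, seeded
  explicitly; identical seeds give identical record lists.

What the simulator does **not** emulate: cause-specific mortality (no
published cause breakdown to calibrate against — only an all-cause
hazard is exposed), litter structure, spatial movement, dam behaviour,
measurement error in hoof growth beyond the site-level normal, and
detection failure (known-fate models assume detection probability 1).
Passing tests therefore demonstrate correctness of the estimation
machinery under the assumed data-generating process, not robustness of
the field method to violations of those assumptions.

## Encounter histories

Histories live on the estimated-age timeline.  An animal of estimated
class `c` enters on age day `c+1`; an event `t` calendar days after
capture maps to estimated age day `c+t`.  Events mapped past the horizon
count as survival to the horizon.  Occasion blocks are inclusive day
ranges; an event on a boundary belongs to the block containing its day.
Weekly blocking is phase-wise — `floor(len/7)` 7-day blocks per phase
(days 1–30, then 31..horizon) with the short remainder merged into the
last block — giving 4 weekly occasions over 30 days (1–7, 8–14, 15–21,
22–30) and 16 over 120 days (final block 108–120).  This is the only
blocking consistent with a weekly model having 4 parameters per group at
30 days and 16 at 120.

A censored animal counts as surviving every occasion from entry through
the occasion containing its censor day, mirroring MARK's LDLD coding
where the censoring occasion is the last `10` pair.  A consequence is
that censoring in the final occasion is indistinguishable from survival
to the horizon (identical rows and identical likelihood contributions);
the `.inp` parser resolves such rows as survivors.  Animals whose
truncated estimated age already exceeds the horizon are excluded with a
warning (impossible for the registered calibrations at realistic hoof
growth, but defined).  Deaths detected in the weekly monitoring phase
use the recorded (midpoint) day as-is when mapped to a block.

## Known-fate likelihood and fitting

With `n_j` animal-occasion exposures and `d_j` deaths in cell `j` (a
group × time-block combination) and `S_j = logistic(β_j)`,

```
−2 ln L = −2 Σ_j [ (n_j − d_j) ln S_j + d_j ln(1 − S_j) ].
```

Cells are likelihood-separable, so the information matrix is diagonal
(`n_j S_j (1−S_j)`); we still maximise numerically (L-BFGS-B with
analytic gradient, all β started at the logit of the overall empirical
survival, `ftol 1e-14 / gtol 1e-10`), with the per-cell closed form
`Ŝ_j = (n_j − d_j)/n_j` retained in the tests as an independent oracle.
Boundary cells (no deaths, or no survivors) have their MLE at ±∞; the
reported β is clamped at ±15 and flagged, while the log-likelihood is
evaluated at the limit (contribution exactly zero), so the saturated
model's deviance is identically 0.  `K` counts structural cells
(groups × blocks) even when some have zero exposure, matching MARK's
reported parameter counts; empty cells are excluded from estimation.

Conventions chosen where the field literature varies:

* **Effective sample size** for AICc is the total number of
  animal-occasion exposures (MARK's known-fate convention); absolute
  AICc values are therefore convention-dependent and only AICc
  *differences* are compared across software.
* **Deviance** is reported against the saturated cohort × occasion model
  of the same data.
* **Time variation** ("daily"/"weekly" survival) is implemented as fixed
  fully time-varying effects, one β per group × block — the only reading
  consistent with parameter counts like 150 = 5 groups × 30 days.
* **Cumulative survival** over a horizon is the product over blocks of
  the block survival raised to the number of covered occasions; its SE
  comes from first-order propagation on the log scale
  (`var ln T = Σ (m_j/S_j)² var Ŝ_j` with `var Ŝ_j = S_j(1−S_j)/n_j`,
  which vanishes smoothly at boundary cells), and the 95% CI is computed
  on the logit scale and back-transformed.  Degenerate estimates (0 or 1)
  report a point CI.
* **β CIs** are normal-theory on the logit scale; the screening flag
  marks any β whose 95% CI includes zero.

## Model comparison

Akaike weights are computed from AICc differences and are invariant to a
constant shift.  Models within 2 AICc of the best are flagged viable.
Survival contrasts treat cohort estimates as independent (diagonal
variance — the information available when only estimates and SEs are
published); the two-group statistic is `(Ŝ₁−Ŝ₂)²/(SE₁²+SE₂²)` on 1 df
and the k-group form is the quadratic form of successive pairwise
differences on k−1 df.

## Problem sizes

Default test and demonstration cohorts use 80–500 simulated neonates per
cohort and 30- or 120-day horizons; repeated-simulation checks (CI
coverage, the positive-intercept bias direction) use 200 replicates of
80–100 animals.  These sizes bracket the published cohorts (37–76
known-age animals per species) while keeping Monte-Carlo error small
relative to the effects tested.

## Known limitations

* No individual covariates, random effects, or model averaging; the
  candidate set is group partitions × three time structures.
* Contrasts ignore any covariance between cohort estimates induced by
  the same animals appearing in several cohorts; this matches the
  published procedure but understates dependence.
* The group-structure degrees of freedom assume every cohort label is
  observed; cohorts with zero animals are dropped with a warning rather
  than estimated.
* The simulator's hazard is all-cause only, and capture is independent
  of fate (no left-truncation bias beyond the modelled staggered entry).
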