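# Methods

## Study design the package models

Five animals, each carrying catheters in the abdominal aorta (ART), portal
vein (PV) and hepatic vein (HV), sampled at 0 (fasting), 60, 180, 330 and
510 min after a meal, on two study days: D0 (healthy) and D60 (after an
obesogenic diet). Metabolite features come from ¹H-NMR spectra reduced to
0.01-ppm buckets over 8.5–0.5 ppm with the residual-water window
(4.5–5.1 ppm) removed and every spectrum normalized to its own total area.
Annotated metabolites are quantified by summing the buckets of a
non-overlapping signal interval; the sum is proportional to the integrated
peak area. Any fixed normalization constant cancels in the arteriovenous
ratios, so the normalization target is 1.

## Exchange statistics

Per metabolite, animal, day and time point:

* intestine: `%induction = (Art/PV − 1)·100`
* liver: `%induction = ((w_a·Art + w_p·PV)/HV − 1)·100` with flow weights
  `(w_a, w_p) = (0.2, 0.8)` (configurable).

Positive = net uptake, negative = net release; the steady state
(inflow/outflow = 1) maps to 0%.

Whole-period quantities per metabolite × animal × day:

* **AUC exchange** — trapezoid AUCs of the inflow and outflow
  *concentration* curves over 0–510 min, with the hepatic inflow composite
  formed pointwise in time *before* integration; the induction formula is
  then applied to the AUC pair. This ratio-of-AUCs definition keeps the
  statistic structurally identical to the per-time formula; the AUC of the
  induction curve is computed separately for the fasting comparison.
* **Fasting comparison** — the induction curve's AUC divided by the
  510-min window (a time-averaged induction) against the fasting (T0)
  *induction*, paired across animals. The fasting reference is the T0
  induction, not the T0 concentrations, because the comparison asks
  whether the meal changed the exchange.
* **Max delta** — the signed excursion `induction(t*) − induction(0)` at
  the postprandial time `t*` maximizing the absolute excursion. Signed,
  because negative inductions (release) are meaningful.

All tests are two-sided paired t-tests across animals at α = 0.05 (per-time
inflow-vs-outflow, AUC inflow-vs-outflow, fasting comparison, and D0-vs-D60
comparisons of the fasting induction, the AUC exchange and the delta). An
all-zero difference vector returns p = 1 by convention — null cohorts
legitimately produce exact zeros. Per-time tests are reported without
multiplicity correction (they populate descriptive tables); the
feature-selection and screening steps do correct, see below. Testing
inflow vs outflow is equivalent under the null to testing induction ≠ 0,
and is what the per-time significance flags mean here.

Differential-exchange counting compares D0 vs D60 per metabolite and organ
either on the fasting induction (`mode="fasting"`) or on the whole-period
AUC exchange (`mode="postprandial_auc"`), counting paired-t p < α.

## Multilevel chemometrics

Repeated measures (times × vessels × days within each animal) are handled
by the multilevel decomposition `X = grand_mean + between + within`, where
`within = X − subject means`. Discriminant models are fitted on the within
matrix; cross-validation folds keep all rows of one animal together
(row-level folds would leak subject identity), which caps the fold count
at the number of animals when grouping is requested. Label permutations in
the permutation tests are performed within animals, preserving each
subject's label multiset.

Numerical choices:

* **PLS-DA**: NIPALS PLS2 against one-hot class membership, convergence
  tolerance 1e-10, at most 1000 iterations per component; components
  requested beyond the rank of X are truncated with a warning. R2Y is the
  explained fraction of centered-Y variance; prediction is the argmax over
  predicted class memberships.
* **Sparse PLS-DA**: per-component soft-thresholding of the X-weight
  vector so that exactly `keepX` variables stay nonzero (the L1-style
  selection used by the mixOmics family); `keepX = p` reproduces the dense
  fit exactly.
* **VIP**: `VIP_j = sqrt(p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a)` with
  `SS_a = ‖t_a‖²‖q_a‖²`; `Σ_j VIP_j² = p` for dense fits. Selection
  threshold 0.8.
* **OSC**: Wold-style — an iterated X score orthogonalized against the
  centered class dummies, X deflated by `t·pᵀ`, one component by default;
  the removed score is re-orthogonalized after convergence so its cosine
  with every class column is < 1e-6 exactly, not just approximately.
* **Scaling**: Pareto (divide by √SD) before PLS models — standard for NMR
  intensities, where unit-variance scaling over-amplifies noise buckets;
  unit-variance autoscaling before hierarchical clustering. Sample SD uses
  n−1. Zero-variance columns are dropped with a warning.
* **Cross-validated Q²** = 1 − PRESS/TSS pooled over folds, TSS measured
  against each training fold's class means; 7 requested folds.
* **Permutation p** uses the +1-corrected estimator
  `(1 + #{null ≥ observed})/(1 + n_perm)`, never exactly 0; 200
  permutations for the PLS-DA Q² test and 100 for the sPLS-DA AUC test by
  default.
* **Kruskal–Wallis** uses mid-ranks with the tie-correction factor and the
  chi-square upper tail; all-identical variables get H = 0, p = 1.
  Benjamini–Hochberg step-up adjusts across variables; the grouping
  variable is an explicit argument (time, vessel or day, by analysis).
* **Sign convention**: every weight/loading vector is oriented so its
  largest-magnitude element is positive, making fits reproducible.

## Feature selection, clustering, outcome correlation

A feature is "postprandially responsive" in a (vessel, day) stratum if any
postprandial time differs from T0 by paired t-test after BH correction
across features within that (vessel, day, time). A Kruskal–Wallis route
across the five time points is selectable.

The clustering input is the features × condition-means matrix (means over
animals per vessel × day × time). Features are auto-scaled across
conditions, then rows and columns are clustered with Ward linkage on
Euclidean distances (scipy's `ward`, the ward.D2 convention); constant
rows are dropped. Output is the merge sequence, heights, leaf order and
cluster assignments at small cuts — deterministic for fixed input.

Outcome correlation pools the per-animal AUC exchange values of both days
(n = animals × 2) and computes Pearson r of **|AUC|** against HOMA-IR or
body weight: the absolute value treats release (negative AUC) and uptake
(positive AUC) changes alike. Metabolites whose day-mean AUC switches sign
between D0 and D60 are excluded (|AUC| would misrepresent their change);
the rule is evaluated on day-level means across animals, with a stricter
per-animal variant behind a flag. Within-animal dependence of the pooled
points is acknowledged and not modeled (plain Pearson by design). The
top-10 report ranks by |r| with alphabetical tie-breaking.

## Synthetic cohort generator

The generator is the pipeline's testbed: it produces cohorts with the
statistical structure the analysis assumes, plus the ground truth needed
to verify every estimator.

Per metabolite m, animal i, day d, time t:

```
A  = baseline_m · re_i · (1 + amp_m · k(t))          arterial curve
PV = A · (1 − e_int[m, d, t])                        intestinal extraction
HV = (0.2·A + 0.8·PV) · (1 − e_liv[m, d, t])         hepatic extraction
```

* `k(t) = ((t/tp)·exp(1 − t/tp))^shape` — a gamma-shaped meal-response
  kernel with `k(0) = 0`, peak 1 at `tp` (per-metabolite, 60 or 180 min by
  default) and relaxation toward fasting by 510 min; shape 2 by default.
* `re_i = exp(N(0, animal_sd))` — between-animal random effect
  (default SD 0.15); it multiplies all vessels alike and therefore cancels
  exactly in the induction ratios.
* every observation carries multiplicative log-normal noise
  `exp(N(0, noise_sd))` (default SD 0.10, a realistic ~10% CV for NMR
  bucket intensities); positivity is preserved, as the ratio formulas
  require.
* extraction fractions are bounded at |e| ≤ 0.9; with zero noise the
  measured induction equals `100·e/(1−e)` exactly, for both organs —
  the closed form every recovery test checks.
* the diet effect is purely a change in extraction profiles between
  `e[m, D0]` and `e[m, D60]`; the default cohort shifts the first third of
  metabolites by ±0.12 (liver) and ±0.08 (intestine) at D60.
* outcomes: `HOMA-IR (or BW) = intercept + Σ_m coef_m·|true AUC_m(day)| +
  N(0, sd)`, floored at a small positive value. The default coefficients
  are calibrated on the day-shifted metabolites so the cohort's mean
  HOMA-IR rises ~0.075 → ~0.41 and body weight ~31.5 → ~44.7 kg between
  days — the magnitude of a diet-induced insulin-resistance phenotype.
  The intercept absorbs the D0 contribution and may be negative.
* bucket embedding: each metabolite occupies one dedicated 0.01-ppm bucket
  (value copied verbatim); other buckets carry low-level positive
  background (level 0.01, log-normal CV 0.3), so total-area normalization
  perturbs metabolite ratios only marginally and rows always normalize.
  The grid holds 740 non-water centers; 594 are kept by default at evenly
  spaced indices (the narrower matrix mirrors typical extra exclusions in
  practice and is cosmetic — the exclusion machinery itself is general).
* all randomness flows through `numpy` generators seeded per operation;
  the pipeline derives per-stage sub-seeds from one run seed via
  `SeedSequence`.

What the generator does **not** emulate: real NMR peak shapes, chemical
shift drift, J-coupling multiplets, peak overlap between metabolites, or
correlated noise between buckets. Passing tests therefore demonstrate that
the statistical machinery is correct under the declared generative model —
not that a real spectral dataset would be processed flawlessly upstream of
the bucket table.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: closed-form recovery
on noise-free cohorts at e ∈ {−0.2, 0.1, 0.25}; 3·sem coverage on 500
replicates of a 5-animal × 50-metabolite default-noise cohort; type-I
calibration on 200 null cohorts × 1,000 paired tests; FDR on 500 mixed
cohorts with 10% true effects; discrimination on a day-shifted 30-metabolite
cohort (multilevel sPLS-DA on log venous concentrations, 200/100
permutations, 100 null-label replicates); association recovery over 100
seeds with outcome signal-to-noise 3; and a double end-to-end run for
byte-identical determinism.

## Known limitations

* The per-time significance flags are uncorrected by design; with many
  metabolites they are descriptive, not confirmatory.
* The liver inflow composite uses fixed flow weights (0.2/0.8); true
  arterial/portal flow partitioning varies postprandially.
* Pearson correlation on pooled D0+D60 points ignores the within-animal
  pairing; with 5 animals the effective n is smaller than 10.
* n = 5 animals puts paired t-tests at the edge of their comfort zone; the
  type-I calibration holds under the generator's log-normal noise but
  heavy-tailed real data may behave differently.
* The arterial curve is identical across days in the generator's default;
  day discrimination therefore lives in the venous samples, and the
  discrimination analyses model those.
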