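# Methods

`regskit` implements a pipeline for predicting drug resistance in B-cell
cancers (diffuse large B-cell lymphoma, DLBCL, and multiple myeloma, MM) from
cell-line screens: (1) growth-rate-corrected dose-response summarisation of
two-timepoint viability plates, (2) cross-drug correlation of resistance
summaries, (3) an elastic-net logistic resistance gene signature trained on
cell-line expression, and (4) resistance-probability stratification of
patient cohorts by molecular subtype and survival.  A synthetic-data module
generates plates, panels, expression matrices and cohorts with known ground
truth so every stage is testable without external microarray data.

## Growth model and dose-response statistics

Untreated cells are assumed to grow exponentially over the 48 h assay window.
With mean control absorbances `A0`, `A48` at the two reads, the control rate
is `r0 = ln(A48/A0)/48` (per hour) and the doubling time `T0 = ln2/r0`.  For a
treated dose `d` the per-replicate rate is computed the same way, and the
*relative growth* is

    g(d) = rate(d) / r0

so `g = 1` means unaffected growth, `g = 0` stasis and `g < 0` net cell
death.  Because `g` is a ratio of rates it does not depend on assay duration
or on the line's intrinsic growth speed — the correction that removes the
classic bias whereby fast-growing lines look drug-sensitive at a fixed
endpoint.  Rates use means over replicate wells per timepoint rather than
per-well pairing, because the 0 h and 48 h readings come from physically
different plates.  Border wells are excluded from every computation (they are
simulated with a +10% evaporation growth bias precisely so that the exclusion
rule is testable).  No blank subtraction is applied by default (an optional
background offset exists but is 0).

A four-parameter logistic in `x = log10 dose`,

    g(x) = lower + (upper - lower) / (1 + exp(slope·(x - midpoint))),

is fitted by bounded least squares with ten starts (slope in {0.5, 2, 8} ×
midpoint at the x-quartiles, plus one data-driven start), ties broken by
lowest SSE then shallowest slope.  The upper asymptote is free and
initialised at 1.  A constant response returns a flat sentinel
(`upper == lower`); all dose thresholds are then censored.

Summary statistics (doses in log10 µg/mL):

* `GI50`: solves `g(x) = 0.5`;
* `TGI`: solves `g(x) = 0`;
* `LC48`: solves `g(x) = -T0/48` (population halves over the window; requires
  growing controls);
* `AUC0`: trapezoid integral of `max(100·g, 0)` over the tested range on a
  ≥1000-point grid — for the default 16-dose two-fold ladder the flat-curve
  maximum is `100·15·log10 2 ≈ 451.5`.

Thresholds are solved in closed form from the fitted parameters; solutions
outside the tested range are clamped to the nearest range edge and flagged
censored (resistant lines sit near log10(500) = 2.70).  Integration limits
are the tested dose range.

Confidence intervals are parametric-bootstrap percentiles (2.5/97.5, default
B = 1000): replicates draw `g* = ĝ(x) + N(0, residual_sd²)` at the observed
design points and refit warm-started at the base estimates; `T0` is resampled
from the control log-absorbance summaries.  Non-converged replicates are
dropped and counted; >20% dropped flags the CI.  Measured coverage of the
95% GI50 interval on simulated noisy plates is within [0.90, 0.98].

## Cross-drug correlation

Resistance co-occurrence between drugs is measured by Pearson correlation of
AUC0 over the cell lines of one disease, with pairwise-complete deletion
(drug panels are unequal), two-sided p-values from the t distribution with
n−2 df, and the significance coding `•/*/**/***` at strictly-less thresholds
0.1/0.05/0.01/0.001.  Pairs with fewer than three complete pairs or a
zero-variance column are reported as skipped.

## Resistance gene signature

Within each disease, lines are ranked by AUC0 and split into tertiles
(sensitive / intermediate / resistant; 14 → 5/4/5, 11 → 4/3/4, middle group
floored, ties broken by stable sort on cell-line name).  The outer tertiles
of both diseases are pooled into a binary outcome (resistant = 1; per-disease
training is available via the `diseases` argument), and an elastic-net
penalized logistic regression is fitted on the internally standardized
expression matrix.

The penalty grid is mixing value `a ∈ {0.1, …, 1.0}` crossed with a 100-point
log-spaced λ path from the all-zero-coefficient λ down to 0.01·λmax (the
standard ratio for p ≫ n).  Tuning is leave-one-out cross-validation with
misclassification at a 0.5 cutoff as the loss; each fold re-standardizes its
own n−1 samples so the left-out line never influences that fold's centering,
scaling or fit.  The λ sequence is computed once on the full training data
and shared across folds.  Ties at the minimum error prefer the larger λ, then
the larger mixing value.  The final model is refit on all included lines
along the chosen path; the signature is the set of nonzero-coefficient
features, and prediction applies the stored training center/scale before the
logistic link.  The solver is a warm-started IRLS/coordinate-descent path
algorithm with an active-set strategy (see `regskit/_enet.py`), validated
against an independent solver in the test suite; the fit path is fully
deterministic, so no random seed enters training.

Two calibration facts worth knowing.  First, LOOCV misclassification on
~18 lines is coarse (granularity 1/18) and the error surface is heavily
tied, so the tie-break rule materially shapes the selected model.  Second,
the reported cross-validation error is the grid *minimum* over ~1000
(mixing, λ) points and is therefore optimistically biased on null data: on
label-permuted training sets its median sits near 0.44 rather than 0.5.
Tests assert it stays ≥ 0.4 — a margin of roughly one misclassified line,
and a quantity whose seed-to-seed spread straddles that bound.

## Cohort stratification

Patient samples are assigned to the molecular subtype with the highest
classifier probability; the `ceil(0.15·n)` samples with the lowest maximum
class probability per cohort are relabelled unclassified (ties broken by
stable sample order).  "Lowest classification probability" is read as lowest
*maximum* class probability, the only reading compatible with argmax
assignment.  Unclassified samples are kept as their own category in group
comparisons.

Resistance probabilities are compared between subtypes with a tie-corrected
Kruskal-Wallis test (chi-square approximation, k−1 df; exact enumeration of
group assignments available for n ≤ 10 — note the chi-square approximation
is accurate in the significance tail but can deviate by ~0.1 mid-range at
such n).  For survival, cohorts are trichotomized into within-cohort
tertiles of predicted resistance probability (cutpoints recorded in the
output); Kaplan-Meier curves are estimated per group and compared with the
k-group log-rank test.  Zero-event tables flag the test undefined.

## Synthetic data

The generators reproduce the statistical structure the analysis assumes:

* **Plates** — 8×12 geometry, interior rows 2–7 / columns 2–11; 16 ladder
  doses × 3 wells in columns 2–9, vehicle controls in interior column 10;
  every border well carries a cycled dose and `is_border = 1`.  Well signal
  is `seeding_signal·exp(rate·t)` with `rate = G(d)·ln2/T0` and `G` the same
  4PL the fitter assumes (so noiseless plates are recovered exactly);
  additive Gaussian absorbance noise truncated at zero (default sd 0.01,
  ~2–5% of signal, matching plate-reader behaviour and keeping log-rates
  defined); border wells grow 10% faster.  An optional lag-phase term
  mis-specifies the model for robustness tests.  The published screens state
  no plate geometry or control-well count; these defaults are declared, not
  inferred.
* **Panels** — truth parameters drawn uniformly from ranges matching the
  published 25-line screen: T0 24–70 h, GI50 0.5–2.05 log10 µg/mL, Hill
  slope 1.5–5, growth floor −1.2 to −0.3, seeding signal 0.15–0.35.
* **Expression** — log2-scale matrices with gene baselines N(7, 1) and unit
  within-gene noise; planted genes are shifted ±effect_size per class
  (resistant +, sensitive −, random sign per gene; intermediates at the
  midpoint), i.e. a between-class difference of twice the effect size.
* **Cohorts** — standardized expression noise moved along the signature's
  coefficient direction so each subtype's logit of resistance probability is
  shifted by a specified amount; subtype class-probability rows are Dirichlet
  draws concentrated on the true subtype; survival is exponential with
  hazard ∝ exp(hazard_coef · resistance probability) (baseline median 36
  months) and independent censoring: each sample is censored with
  probability `censor_fraction` at a time uniform on (0, T).

What the simulations do *not* emulate: probe-level microarray structure,
cross-platform batch effects, gene–gene correlation beyond the planted
signature, non-exponential growth (beyond the lag toggle) and informative
censoring.  Passing tests therefore demonstrate correctness of the
computations and calibration of the statistics under the assumed model, not
robustness to real-data violations of it.

## Problem sizes used in tests and the acceptance script

Simulation-based checks use: 50 seeds for noisy-plate recovery, 200 screens ×
400 bootstrap replicates for CI coverage, 25 panel seeds for planted-gene
recovery (10 planted among 2000 genes, effect 3), 15 label permutations for
the null cross-validation check, 500–1000 simulations for the type-I error of
the correlation, Kruskal-Wallis and log-rank tests, 200 for log-rank power,
and n = 300 patients for the end-to-end cohort comparison.

## Known limitations

* The 4PL form and the parametric bootstrap scheme are declared design
  choices validated by consistency properties against the published summary
  table, not derived from the original screening protocol.
* Tertile labels discard the resistance ranking's ordinal information; the
  intermediate tertile is unused at training time and has no special handling
  at prediction time.
* Coefficients are reported on the standardized-expression scale; applying a
  signature across platforms assumes comparable normalization (a per-cohort
  re-standardization mode is deliberately not applied by default).
* The exact-permutation Kruskal-Wallis is limited to n ≤ 10 (enumeration
  grows multinomially).
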