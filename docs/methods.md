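# Methods

This note records the modeling choices, defaults, and known limits of the
toolkit. Notation: cases are outcome 1, controls outcome 0; $\pi$ denotes a
class prior (case proportion); predictors are continuous, covariates binary.

## Preprocessing

Exclusion filters drop rows with implausible total energy intake (<500 or
>4000 kcal/d), triglyceride/AST/GGT above 1000, or fasting glucose outside
(55, 200) mg/dL; all comparisons are strict so boundary values survive, and
missing-data handling is complete-case. Filtering is idempotent and logs
per-rule removal counts in application order.

Nutrient intakes are energy-adjusted by the Willett residual method: each
nutrient is regressed on total energy and replaced by residual + fitted
value at the sample-mean energy, preserving the nutrient's scale and sample
mean exactly. The add-back constant is the standard choice; fitting is done
on whichever table is passed in — the default workflow adjusts the full
pre-split cohort (matching how such cohorts are usually described
descriptively), and callers wanting a strictly leakage-free variant can
adjust the training split only and reuse nothing across the boundary.

LDL is derived by the Friedewald equation, LDL = TC − HDL − TG/5 (mg/dL),
with an advisory validity flag above TG 400 mg/dL; values are still
returned because upstream exclusions already remove extreme rows.

Standardization is control-referenced: per-predictor mean/SD are fitted on
**training controls only** and applied frozen to all rows of all splits, so
case values read as deviations from the healthy population. Zero control SD
is an error naming the predictor.

The 70/30 split is stratified by outcome by default, using per-class floors
with largest-remainder top-up so the training size is exactly
$\lfloor 0.7 n \rfloor$; a 7,652-row cohort with 156 cases gives 5,356/2,296
rows and 109/47 cases. Stratification is an inference from those exact case
counts, not an asserted fact about any external dataset; a plain random
split is available by flag.

EPV (events per variable) is reported unrounded with a 1-dp rendering; with
109 events it is 5.45 at 20 predictors and ranges 9.9 (11) to 3.2 (34).

## PCUSTe

Strata are the joint levels of the matching covariates. For each stratum
with $c_s$ cases, $r\,c_s$ controls are drawn uniformly without replacement
from that stratum's controls with a seeded generator; cases are retained
unchanged; the output is shuffled. Determinism: strata are visited in
sorted key order, so a fixed seed reproduces the draw bit-for-bit.

**Deficit rule** (open design point): when a stratum holds fewer controls
than required, all are taken and the deficit is backfilled by a uniform
draw from the remaining unsampled controls cohort-wide, with a warning
listing per-stratum deficits. This preserves the target size and
approximates the case distribution without sampling with replacement.

## Oversampling

SMOTE synthesizes minority rows $x_i + u(x_{nn} - x_i)$, $u\sim U(0,1)$,
with $x_{nn}$ among the k nearest minority neighbors (Euclidean on the
standardized continuous predictors), generating enough synthetics to reach
a 1:1 prior; seed points cycle through the cases so generation is even.
ADASYN apportions the synthetic budget by each case's normalized fraction
of majority points among its k neighbors in the full set
(largest-remainder rounding); all-zero weights fall back to uniform,
logged. SMOTE+ENN then deletes (simultaneously) every row whose label
disagrees with the majority vote of its `enn_k` nearest neighbors — both
classes eligible, ties keep the row — so the output prior can leave cases
the majority. `enn_k` defaults to 3 (unspecified in the source design;
exposed as a parameter).

k is resolved from a fraction of the minority count:
$k=\max(1,\lfloor f n\rfloor)$ clamped below $n$; floor is the only
rounding consistent with all six reference (fraction, k) pairs at $n=109$.
A single shared k serves both ADASYN's density weights and interpolation.
Synthetic rows copy the seed case's binary covariates — interpolation is
meaningful only in continuous space, which is also why predictor selection
in this workflow is restricted to continuous variables.

These samplers are implemented natively in `pcuste.resampling`; neighbor
ties break by row order for determinism.

## Modeling

The incremental learner is an SGD logistic model: L2 penalty `alpha`
(default 1e-4), constant learning rate `eta0` (default 0.01), one epoch
per partial update, no stopping tolerance; the final iterate is returned
(no averaging — the raw final state is the assumed convention, with
averaging left to callers). Defaults were chosen once as ordinary
magnitudes for standardized inputs. Iteration $i$ of
`train_incremental_pcuste` draws a PCUSTe set with seed $\text{base}+i$;
the log keeps per-iteration control-id sets so coverage is exact, not
estimated.

Prior correction uses the standard odds reweighting (see README formula);
it is a strictly monotone bijection on (0,1) with fixed points at 0 and 1,
an identity at equal priors, and exactly inverted by swapping priors.

Thresholding predicts positive when score ≥ t. The ≥ convention makes the
incidence-only null model (everyone scored at the base rate) all-positive,
matching its definition as the recall ceiling. The default threshold is the
**exact** training incidence (0.02035… for 109/5356) with a 2-dp rendering;
a fixed rounded 0.02 can be passed explicitly.

Cross-validation is stratified k-fold with resampling applied only inside
the k−1 training folds; tuning hooks run inside the fold; the held-out test
split never enters. A deliberate `leak_resample_before_split` mode
reproduces the classic bug for demonstration — on signal-free data it
inflates AUC for flexible learners (validation synthetics sit next to their
training parents), while the leakage-safe path stays at 0.5.

## Evaluation

Metric conventions: MCC is 0 whenever any denominator factor is 0 (making
the null row exactly 0); PPV/NPV with no predicted positives/negatives
report 0 with a flag; weighted F1 is the class-support-weighted mean of
per-class F1. AUC is the Mann–Whitney rank statistic with half-credit
ties. Bootstrap CIs are percentile (2.5/97.5) over plain row resampling —
stratification by class is available by flag but off by default since
stratified resampling was not part of the reference procedure; replicates
missing a class are skipped for class-conditional metrics and counted.
Brier scores are computed on prior-corrected probabilities when correction
is active, matching the calibration intent.

## Diagnostics

PCA (2 components) is fitted on the original training data only and applied
to every resampled set so projections share axes; inputs are already
control-standardized, so no per-feature rescaling is done before the fit.
Distance summaries are exact all-pairs means (within-class means exclude
self-pairs, each unordered pair once). "Resampled vs original" distance
defaults to the all-pairs cross-set mean for consistency with the
case-control definition; a nearest-neighbor variant is behind a flag
because the all-pairs reading is one of two defensible interpretations.
Predictor–outcome association is point-biserial correlation, NaN-flagged
for zero-variance predictors.

## Synthetic cohort generator

The generator emulates the structure of the motivating screening cohort:
n = 7,652, incidence 156/7,652 ≈ 2%, seven binary covariates and 34
continuous predictors with per-class moments from the packaged reference
description. Only marginals are published, so predictors default to
per-class independent Gaussians; an optional correlation matrix can be
supplied but is beyond what the reference reports. Nutrient-type negative
draws are truncated at zero with a logged rate.

`class_conditional` mode reproduces the reference contrasts exactly in
expectation and is the calibration surface for moment checks.
`latent_logistic` (default) draws features from the control distribution,
computes risk $\sigma(a + \beta^\top z)$ on control-standardized features,
draws the outcome, then shifts case rows by the case-control mean
contrasts. The intercept $a$ is root-solved on the realized scores so mean
risk equals the target incidence; exact-count mode selects cases by
Gumbel-top-k weighted sampling on the risks. Default
$\beta = 0.25\,d$ where $d$ is the standardized mean-contrast vector — a
modest latent tilt on top of the deterministic shifts, chosen once to give
a clearly learnable but not trivial signal. Note the selection tilt means
latent-mode case means sit slightly above the configured targets; moment
calibration is therefore asserted in class-conditional mode.
`recoverability_check` standardizes by the *configured* control moments
(the scale $\beta$ is defined on), since observed control moments are
tilted by outcome selection.

**What passing tests do not show:** real cohorts have correlated
predictors, non-Gaussian dietary distributions, and measurement error, so
absolute performance numbers on the synthetic cohort (AUC ≈ 0.89 for the
incremental model) overstate what identical code achieves on real data; the
reference study reports ~0.77 on its private cohort. The toolkit's claims
are about mechanism (stratum-exact matching, coverage, calibration,
leakage-safety), which the tests check exactly or distributionally.

## Problem sizes in tests and the acceptance script

Unit and property tests run on toys and 2,000–5,000-row synthetic cohorts;
coverage/reproducibility checks use the full 7,652-row cohort with 1,000
iterations; generator calibration uses n = 100,000; the leakage check uses
50 replicates of n = 200; bootstrap coverage uses 200 simulations of
n = 500 — sizes chosen so the whole suite completes in well under a minute
of compute per heavy check while keeping Monte Carlo error far below the
asserted tolerances.
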