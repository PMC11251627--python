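# Methods

`mstraj` implements a complete analysis pipeline for longitudinal
Expanded Disability Status Scale (EDSS) data in multiple sclerosis:
trajectory descriptors, consensus course labelling, prediction of the
descriptors from baseline features, and Shapley-value explanation of
the fitted models.  Because registry cohorts of this kind are rarely
shareable, the package also ships a synthetic-cohort generator whose
planted structure makes every downstream stage testable.

## The EDSS ladder

EDSS is an ordinal scale from 0 (no disability) to 10 (death from MS)
in half-point categories, with no 0.5 step: the ladder is
0, 1.0, 1.5, ..., 9.5, 10.0 — twenty categories.  All descriptor
arithmetic runs on the ladder *index* (0..19), never on raw score
differences: a change is weighted 0.5 per category crossed, increasing
or decreasing alike, so 2.0 → 3.0 counts +1.0 and 1.5 → 0 counts −1.0
(two categories, because 0.5 does not exist).  Off-ladder inputs are
rejected, not rounded — silent coercion would corrupt the step
weighting.  An alternative raw-score convention is available through
`delta_convention="raw_score"` in `weighted_delta`; the category-step
convention is the default and is the single most consequential reading
of the weighting rule, which is why it is isolated in one function.

## Trajectory descriptors

For a patient with assessments (T_0=0, ..., T_n) and scores
EDSS_0..EDSS_n, with w(a, b) the weighted category change:

* **β1** = w(EDSS_0, EDSS_n) / (T_n − T_0): the end-to-end slope in
  category-step units per day.  Intermediate visits are ignored by
  construction.
* **β2** = Σ_{i=1..n} [w(EDSS_{i−1}, EDSS_i) / (T_i − T_{i−1})] ×
  (T_n − T_{i−1}): each segment's rate of change is amplified by the
  time remaining to the last assessment, so early changes dominate.
  Two published forms of this sum disagree (a common ΔT factor versus
  the per-term remaining time); this package implements the expanded
  per-term form, and the two-point identity β2 = w(first, last) —
  the factors cancel exactly at n=1 — is enforced by test.
* **EDSS(t)**: the categorical value at horizons 0, 1, 2, 5 and 10
  years (365 days/year).  Horizon 0 is always the first assessment.
  Otherwise: (a) the nearest assessment within ±90 days wins (ties go
  to the earlier visit, favouring the already-observed state); (b) if
  no assessment is that close but the horizon is bracketed by a
  previous and a subsequent assessment carrying the same score, that
  shared score is imputed — the three-month stability assumption that
  a value matching both neighbours did not change in between; (c)
  otherwise the horizon is missing.  The published wording of the
  stability rule is ambiguous about what the three-month interval
  constrains; this package reads the ±90-day window as the matching
  tolerance of branch (a) and applies branch (b) whenever the brackets
  agree, which reproduces all the worked cases we could construct.
  Missing is a value, not an error.

The ≥6 pooling of high EDSS categories applies only to count matrices
and classification targets, never to descriptor arithmetic.

## Inclusion criteria and course labels

Patients enter the analysis with ≥2 EDSS assessments, ≥365 days
between first and last assessment (365, not 365.25 — configurable; no
convention is standard), and a baseline MRI.  Exclusions are counted
by the first matching reason in that order.  Disease onset is proxied
by the first assessment throughout; series days are anchored there.

Consensus severity labels: *aggressive* if any assessment within the
first 10 years reaches EDSS ≥6.0 (decisive regardless of later
course); *mild* if follow-up reaches 10 years and the 10-year value
(EDSS(10), falling back to the last observed score) is ≤3.0; *average*
for decided patients meeting neither criterion; *ineligible* when
follow-up is under 10 years and 6.0 was never reached.  The average
group is the complement of the two criteria rather than a third
explicit rule.  Two β1 cut points (mild/average, average/aggressive)
are fitted as midpoints between adjacent group extremes when the
groups separate cleanly, otherwise as the exhaustive 1-D split with the
fewest training errors (ties to the smaller threshold).  In the binary
evaluation, aggressive is the positive class and mild∪average pool as
negative — the clinically interesting detection target.

## Prediction protocol

Seven tasks per cohort: β1 and β2 regression, EDSS(t) classification at
five horizons.  Features are the baseline-MRI findings plus sex
(one-hot) and age at onset; descriptor and label columns are barred
from the design matrix.  Classification targets pool ≥6 into one class
and drop classes with fewer than 10 occurrences (with their rows);
fewer than two surviving classes aborts that task only.

Evaluation uses a stratified 80/20 train/test split and 5-fold
cross-validation on the training part (stratified for classification;
plain shuffled K-fold for regression, where stratification has no
meaning).  Metrics: MAE for regression; macro one-vs-rest AUC-ROC,
macro sensitivity, accuracy and macro precision for classification
(macro because no averaging convention is standard for a single
reported number; weighted averaging is a switch).  Every metric is
reported for train and test, and gaps above 0.15 (absolute) are
flagged as potential overfitting.

Baselines are ordinary least squares (ridge-stabilised when the design
is singular) and multinomial logistic regression behind median
imputation and standardisation; the boosted models are XGBoost with
missing-value support, evaluated both at library defaults and after
Bayesian hyperparameter search.  The search is an in-repo
Gaussian-process expected-improvement optimiser (Matern-5/2 surrogate
over the unit-cube encoding, log scales where appropriate) over:
depth 2–10, learning rate 10⁻³–0.3 (log), 50–600 trees, min child
weight 1–10, subsample and colsample 0.5–1, γ and L1 10⁻⁸–5 (log),
L2 10⁻²–5 (log); the objective is cross-validated MAE (regression) or
negative mean macro AUC (classification) on the same folds used
everywhere else.  The library-default configuration is always the
search's first trial, so the tuned configuration can never have worse
CV loss than the default — the tuned-versus-default ordering is
structural, not luck.  Default budget is 50 evaluations; the bundled
analyses and acceptance checks use 25 (and 10 for the secondary β1
explanation model), which the search-convergence behaviour on these
problem sizes justifies.

The EDSS(0) task is retained despite its leakage flavour (baseline
features predicting baseline state): it is part of the task suite this
pipeline mirrors and its behaviour is informative about how much of
the baseline state the features encode.

## Shapley explanation

Attributions are computed in margin (log-odds) space, where additivity
is exact for tree ensembles: tree models go through the boosting
library's exact tree-path contribution algorithm, linear models through
the closed interventional form φ_j = coef_j·(x_j − E[x_j]) with the
explained sample set as background.  Local accuracy (base + Σφ = model
margin) is asserted to 1e−4 relative.  Importance is the mean
|attribution| over samples, and over classes for classifiers; ties in
the ranking break lexicographically.  Probability-space attribution is
out of scope.  Exhaustive subset enumeration of the Shapley definition
exists only as a ≤3-feature test oracle, never in the production path.

## The synthetic generator

`generate_cohort` draws, per patient: a binary causal lesion feature
("Nb lesions/Brain (> = 9)", prevalence 0.30); a severity group
(mild/average/aggressive, base weights 0.45/0.42/0.13) whose
*aggressive* odds are multiplied by exp(feature_effect) when the causal
feature is present — so the feature→aggressive odds ratio is
exp(feature_effect) by construction, a closed-form self-check — and
whose average-vs-mild odds tilt with age at onset; a latent drift in
category steps/year (group means 0.05/0.35/1.3) scaled by
exp(0.8·z_age), damped ×0.6 for pediatric onset (<20 y), and boosted
×exp(0.5) when the causal feature co-occurs with spinal involvement; a
baseline EDSS index driven by lesion-*pattern* burden (isolated
findings contribute little, co-occurring findings compound, plus a
lesion-volume threshold step) with a small gamma remainder; visit days
from a Poisson process (1.5/year) over a follow-up drawn uniformly from
1–30 years, always including day 0 and the final day, capped at 40
assessments; transient relapse excursions (0.2/year, +2 categories
decaying over 90 days); and ±1-category observation jitter on 10% of
visits.  A panel of 17 baseline-MRI features is emitted; all but the
causal one are drawn independently of the severity group.

Two independent random streams separate cohort *structure* (groups,
drifts, baselines, visits) from *noise* (nuisance features, relapses,
jitter, sex), so changing only the noise seed never changes the
ground-truth labels.

Defaults were chosen once to emulate the registry structure the
pipeline targets: n=446 patients, visit-score mass concentrated below
EDSS 4.0 (the generator keeps >60% of visit scores under 4.0 at scale),
and 2–40 assessments per patient over 1–30 years.  The interaction
terms in burden and drift are planted deliberately: they are the
mechanism by which interaction-capable learners (boosted trees) hold a
representational advantage over the additive logistic baseline, which
is the model-ordering property the synthetic data must exhibit for the
pipeline's comparisons to be meaningful.  What the generator does *not*
attempt: fitting the real cohort's printed moments, relapse-rate
realism (monotone latent drift plus transient excursions is a
simplification of MS natural history), treatment effects, or missing
feature values.  Passing tests therefore demonstrate that the pipeline
recovers structure of this planted kind, not that it would achieve any
particular performance on clinical data.

## Numerical choices and degenerate inputs

Days are floats anchored at 0; same-day duplicate visits keep the
last-entered value with a warning.  Horizon days use round(h·365).
Threshold-fit ties resolve to the smaller split; nearest-visit ties to
the earlier visit.  A class absent from one side of an evaluation set is
excluded from macro averages (logged).  Single-class truth makes AUC
undefined (reported as NaN, never fabricated).  Per-patient descriptor
failures (e.g. a single-visit series) become flagged rows, not aborts;
per-task domain errors (too few classes) are recorded in the
experiment bundle.  All estimators are seeded; XGBoost runs
single-thread `hist` for bit-reproducibility.

## Problem sizes used in bundled checks

The acceptance checks run the full pipeline at n=800 patients per
cohort over five seeds with search budget 25 (10 for the β1
explanation model), the generator self-checks at n=2000, and the
descriptor oracle comparison on 1,000 random ladder walks of length
2–40.  These sizes give stable medians for the stochastic quantities
while keeping a complete run in the minutes range; they are stated
here so results are read at the scale they were computed.

## Known limitations

* The stability-imputation reading of the three-month rule is one of
  several defensible interpretations; the branch logic is isolated in
  `edss_at_timepoints` and windowing is configurable.
* β2 inherits the descriptor family's assumption that all category
  transitions are equally costly; it is also sensitive to relapse
  transients near the start of follow-up (long remaining-time factor).
* The generator's group structure makes mild-versus-average membership
  only partially recoverable from features by design; macro AUC well
  below 1 on synthetic EDSS(t) tasks is expected, not a defect.
* Class imbalance is handled by stratification only; no resampling or
  reweighting.
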