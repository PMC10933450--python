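# Methods

## The problem

Temporal lobe epilepsy (TLE) presents clinically as one entity but its
gray-matter pathology is heterogeneous: atrophy can begin in either
hippocampus or in the neocortex, and a sizable minority of patients show no
atrophy at all but an enlarged amygdala. Because longitudinal imaging over a
disease course of decades is rarely available, this package infers
*pseudo-longitudinal* atrophy trajectories from cross-sectional regional
morphometry using a z-score event-based subtype-and-stage model, then asks
whether the resulting subtypes carry prognostic information for surgical
versus pharmacological treatment.

## Normative z-scoring

Each regional measure (subcortical volume, mm³; cortical thickness, mm) is
regressed on sex, age, age², and total intracranial volume **in healthy
controls only**; applying a control-estimated model to patients is the
normative convention and avoids leaking patient atrophy effects into the
covariate adjustment. A patient's z-score is the residual from the control
prediction divided by the control residual sd, multiplied by −1 so that
**larger z means more tissue loss**; enlargement (e.g. amygdala) shows as
negative z. Age is centred on the control mean before squaring to reduce
collinearity (configurable off). Residual sd uses the regression residual
with denominator n−5, not the raw control sd — this is what makes the score
a normative deviation. A residual sd below 1e−8 raises a degenerate-ROI
error rather than producing huge z-scores silently.

With n = 81 controls, coefficient estimation error inflates the patient
z-score variance by roughly 10–20% over the generative unit variance
(measured on synthetic data); properties that assert unit-variance closure
therefore use larger control samples (n = 500).

## The progression model

An *event* is a (region, z-threshold) pair; thresholds default to the
waypoints z = 1, 2, 3 for all regions. A *trajectory* is a permutation of
all E events respecting each region's threshold order. Between its anchors
(stage 0, z = 0), (position of each threshold event, threshold) and (stage
E, `z_max`), a region's expected z rises piecewise-linearly; `z_max`
defaults to 5 (an expected ceiling above the last waypoint; configurable —
the quantity is not identified by the data and only shapes the final
segment). If a region's last event occupies the final position, the
threshold anchor takes precedence over the `z_max` anchor at that stage.

A subject's likelihood marginalizes a diagonal Gaussian observation model
(σ_b = 1 by default, justified because inputs are normative z-scores;
configurable per region) over a uniform prior on the integer stages 0..E.
Subtypes form a mixture over C trajectories with fractions f_c. All
likelihood code funnels through one evaluator that expands the Gaussian
quadratic form into a single BLAS product plus a fused numba kernel; the
same public functions are retained in plain numpy/scipy form and the test
suite cross-checks the two paths.

## Fitting

**Single trajectory.** Multi-start greedy hill-climbing: from a random
valid ordering, every valid relocation of every event is tried and the best
improvement accepted, until no move improves. Reference budget is 25
starts; the desk-scale profile uses 2.

**Mixture.** Hierarchical construction: the (k−1)-subtype solution's
clusters are each candidate-split and the split with the highest mixture
likelihood is kept. A candidate split bipartitions a cluster's members,
fits each half greedily, then runs hard expectation-maximization over *all*
subjects (reassign → update fractions → refit each cluster's ordering by
hill-climbing from its current ordering) until the assignment stabilizes.
Two implementation choices matter at desk scale and are deliberate
deviations from the simplest scheme:

* *Residual-guided split seeding.* Purely random bipartitions of ~150
  members essentially never concentrate a 14% minority subtype, so the EM
  rarely finds the third (cortical) trajectory from random seeds alone.
  Each split therefore adds structured candidates to the random ones:
  2-means on the members' residuals from the parent trajectory at their
  MAP stage, both on the raw residuals and on their top one and two
  principal components (PCA denoises the per-subject noise that otherwise
  drowns the coherent misfit direction a different ordering leaves).
* *Local-then-global split refinement.* Each candidate 2-mixture is first
  refined by hard EM on the split cluster's members alone — so the
  separation is not washed out by the other clusters' subjects — and only
  then enters the global EM over all subjects.
* *Budgeted candidate EM, full polish of the winner.* Hill-climbing inside
  candidate EM is capped at one pass per refit; the winning solution at
  each k is then re-converged with uncapped EM. This spends the compute
  where it matters and keeps the classification log-likelihood monotone
  within every EM run.

**Uncertainty.** Metropolis MCMC over orderings: per iteration one subtype
is chosen uniformly, one of its events relocated to a uniformly chosen
valid position, and the move accepted with min(1, exp Δlog L); fractions
stay fixed so the chain is a pure ordering sampler. Every 10th state is
stored; the maximum-likelihood state over the chain becomes the reported
ordering. Positional-variance matrices (event × position frequencies)
summarize ordering uncertainty. Reference budget 10⁶ iterations; desk
profile 10⁴.

**Model order.** CVIC: plain k-fold split (default 3 folds at desk scale),
per fold and k the model is refitted on the training folds and the test
log-likelihood averaged over MCMC ordering samples; CVIC(k) = Σ_folds −2 ×
out-of-sample log-likelihood, minimized over k.

**Assignment.** Subtype posterior from the mixture; MAP stage within the
MAP trajectory. A subject whose modelled z-scores are all below 1 is staged
0, and any stage-0 subject is labelled "normal" — with all regions at their
baseline anchor, trajectory membership is undefined.

## Characterization statistics

Stage–atrophy coupling uses Spearman correlation per trajectory (normal-
labelled subjects carry no stage and are excluded). ROI-wise group
contrasts are two-sided pooled-variance t-tests (Welch configurable) with
Benjamini–Hochberg FDR across regions. Clinical comparisons follow the
one-vs-all and pairwise scheme: one-way ANOVA with unadjusted LSD pairwise
t-tests on the pooled error term for continuous variables, Pearson
chi-square *without* continuity correction for categorical ones (the
uncorrected statistic is what reproduces the published 2×2 values), FDR
within each variable's family. Seizure-freedom rates exclude subjects lost
to follow-up from every denominator and are compared one-vs-rest by 2×2
chi-square per treatment arm.

## Prognosis classifier

On operated patients with known outcome, features are one-hot-encoded
clinical variables, optionally plus the regional z-scores. Inside every
fold of a ten-fold cross-validation, features are z-standardized and
reduced by PCA to the smallest component count explaining ≥ 95% variance —
both fit on the training rows only. The stratified model trains one
support-vector classifier per subtype and predicts held-out subjects with
their own subtype's classifier; the pooled baselines train a single
classifier on the same folds, so comparisons are paired. The kernel
(linear / RBF / polynomial) is selected per stratum by inner 5-fold
cross-validation unless fixed by config. Training is unweighted by default
(class weighting is opt-in), consistent with the low pooled sensitivity
regime the stratified model is meant to beat. Performance is summarized by
sensitivity, specificity, accuracy and the Youden index J = sensitivity +
specificity − 1; significance comes from rerunning the *entire*
cross-validation on permuted outcome labels, p = (1 + #{J_perm ≥ J_obs}) /
(1 + n_perm), default n_perm = 1000 (desk scale 200). A stratum whose
training fold is single-class is skipped with a warning and excluded from
pooled metrics.

## Synthetic cohort generator

The raw study data are protected, so a generator reproduces the structure
the analysis assumes; its defaults are the study conditions, not tuning
knobs:

* 296 patients / 81 controls; subtype fractions 28.7 / 38.2 / 13.9 /
  19.2% allocated by largest remainder (85/113/41/57 at n = 296).
* Three generating orderings whose first events are pinned to (left
  hippocampus, z=1), (right hippocampus, z=1) and (frontal cortex, z=1);
  the remaining order is randomized per seed under threshold-order
  validity.
* Controls: age ~ N(26.4, 6.7) truncated to [18, 60] years, sex
  Bernoulli(½), TIV ~ N(1470, 140) cm³; raw measures follow a linear
  covariate model with plausible single-scanner scales (hippocampus ≈ 4000
  mm³, thickness ≈ 2.5 mm; age slope −0.002 mm/yr on thickness, TIV share
  on volumes) and Gaussian noise (5% of volume, 0.1 mm thickness). These
  slopes are documented defaults; no test depends on their values.
* Trajectory patients: stage uniform on 1..E (the model's own prior —
  no stage distribution is published), modelled z ~ N(g[b, stage], 1).
  "Normal" patients: modelled z upper-truncated below 1, bilateral
  amygdala z ~ N(−1.5, 0.8) (an enlargement stand-in on the z scale; the
  published evidence is a large t-statistic, not an effect size).
* Latent z maps back to raw measures by inverting the generator's own
  covariate model, so the pipeline's regression step is genuinely
  exercised.
* Clinical columns (onset age per subtype, lateralization, hippocampal-
  sclerosis and febrile-history rates, treatment-arm shares) and
  per-(subtype, arm) seizure-freedom probabilities follow the published
  per-subtype summary table; loss to follow-up is thinned per arm.

What the generator does **not** emulate: site/scanner effects, spatial
correlation between neighbouring regions, non-Gaussian measurement error,
stage-dependent covariate drift, and correlation between stage and
clinical covariates beyond subtype membership. Passing recovery tests
therefore shows the pipeline is correct and identifiable under its own
assumptions — not that real TLE cohorts satisfy those assumptions.

## Identifiability limits worth knowing

At stage 0 and at the final stage every trajectory predicts the same
z-profile (all baseline / all ceiling), so subtype membership is
intrinsically ambiguous at the stage extremes; with unit noise the
achievable label recovery for three trajectories with randomized tails and
uniform stages is ≈ 85–90% even under the generating model. Recovery
assertions are calibrated against that generative ceiling, and the
well-separated two-cluster test uses opposed "staircase" orderings and
mid-range stages, where separation is essentially perfect.

## Problem sizes used by the shipped runs

The numbered analysis scripts and the test suite run the desk-scale
profile: 2 greedy starts, 2 random + 3 residual-guided bipartitions per
split, 10⁴ MCMC iterations (1.5×10³ inside CV), 3 CV folds, 200
permutations. Reference-scale settings (25 starts, 10⁶ iterations, 1000
permutations) are plain configuration changes and alter no code path.

## Known limitations

* The event-based model assumes monotone progression and a shared ordering
  within subtype; regression of atrophy or measurement drift violates it.
* σ_b = 1 treats the normative residual scale as exact; with small control
  samples the effective noise is slightly larger.
* CVIC at 3 folds with short chains is noisy for closely competing k; the
  reference budget sharpens it.
* Hard EM can empty a cluster on adversarial data; emptied clusters are
  dropped from the mixture rather than resurrected.
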