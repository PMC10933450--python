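# tlesustain

Subtype-and-stage inference of gray-matter atrophy progression in temporal
lobe epilepsy (TLE), from cross-sectional MRI morphometry to
treatment-outcome prediction.

## What it does, and for whom

Around 40–50% of drug-resistant TLE patients fail to reach long-term
seizure freedom after anterior temporal lobectomy, which suggests TLE is
not one disease. This package is for imaging/biostatistics researchers who
want to stratify a TLE cohort from a single MRI per subject:

1. **Normative z-scoring** — each regional measure (subcortical volume,
   cortical thickness) is regressed on sex, age, age² and total
   intracranial volume in healthy controls; patient deviations are
   sign-flipped z-scores (larger z = more atrophy).
2. **Trajectory inference** — a z-score event-based subtype-and-stage
   model: an *event* is a region crossing a z waypoint (z = 1, 2, 3); a
   *trajectory* S is a permutation of all events (threshold order
   respected), giving piecewise-linear expected z per region over integer
   stages k = 0..E. A subject's likelihood marginalizes Gaussian noise
   over a uniform stage prior,

       p(x | S) = 1/(E+1) Σ_k Π_b N(x_b ; g_b(k | S), σ_b²),

   and C trajectories mix with fractions f_c. Fitting is multi-start
   greedy hill-climbing inside a hierarchical cluster-splitting scheme,
   with MCMC over orderings for uncertainty (positional-variance
   diagrams) and CVIC (−2 × out-of-sample log-likelihood, summed over CV
   folds) to choose C.
3. **Subtyping and staging** — each patient gets a maximum-likelihood
   trajectory and stage; patients with all modelled z < 1 are staged 0
   ("normal" subtype, typically showing amygdala enlargement instead of
   atrophy).
4. **Characterization** — stage–atrophy Spearman correlations, ROI-wise
   t-contrasts with Benjamini–Hochberg FDR, one-vs-all / pairwise
   clinical comparisons (ANOVA + LSD, Pearson chi-square), seizure-freedom
   contingency tables per treatment arm.
5. **Prognosis** — a subtype-stratified SVM (one sub-classifier per
   subtype; per-fold standardization + PCA to 95% variance; ten-fold CV)
   against pooled baselines, summarized by the Youden index
   J = sensitivity + specificity − 1 with a label-permutation test.

Because the real patient tables are protected, `tlesustain.synthcohort`
generates cohorts with the same statistical structure — three trajectories
starting at the left hippocampus, right hippocampus and frontal cortex,
plus the normal subtype, in proportions 28.7/38.2/13.9/19.2% — with known
ground truth for recovery testing.

## Worked example

```python
from tlesustain import (make_ground_truth, simulate_cohort, fit_normative,
                        compute_zscores, select_modeling_rois,
                        fit_subtypes, assign_individuals, build_event_set)
from tlesustain.fitting import TEST_PROFILE
from tlesustain import rois

gt = make_ground_truth(seed=11)
morph, clin = simulate_cohort(gt, n_patients=296, n_controls=81, seed=12)

controls = morph[morph.group == "control"]
patients = morph[morph.group == "patient"]
Z = compute_zscores(fit_normative(controls), patients)
Zm = select_modeling_rois(Z, rois.MODELING_ROIS)     # 23 modelled ROIs

es = build_event_set(Zm.rois)                        # 69 events, 70 stages
model = fit_subtypes(Zm.values, es, k=3, config=TEST_PROFILE, seed=0)
assign = assign_individuals(model, Zm.values, subject_ids=Zm.subject_ids)
print(assign.labels.value_counts())
```

prints (desk-scale profile, a few minutes on one core):

```
label
trajectory_1    104
trajectory_2     91
trajectory_3     61
normal           40
Name: count, dtype: int64
```

The three atrophy trajectories and the no-atrophy group emerge near their
generating sizes (85/113/41/57 before label permutation); the "normal" row
holds exactly the subjects with every modelled z-score below 1 (stage 0) —
fewer than the generating 57 because normative-estimation noise lifts some
truly-flat subjects over the z = 1 line. Matching assigned to generating
labels, 85.8% of trajectory-subtype patients recover their generating
trajectory on this run. The numbered drivers under `analysis/` run the same steps end to end
(simulate → z-score → fit/CVIC → characterize → predict) and write their
tables under `results/`.

There is also a CLI: `tlesustain simulate|zscore|fit|assign|characterize|
predict|run`, each a thin wrapper over the functions above.

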