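# Desk-scale demo: synthetic cohort, reduced event space and MCMC budget.
# Run with:  tlesustain run --config configs/demo.yaml --outdir results/demo
seed: 7
simulate:
  n_patients: 300
  n_controls: 81
modeling_rois:
  - Left_Hippocampus
  - Right_Hippocampus
  - Left_Thalamus
  - Right_Thalamus
  - Left_Superiorfrontal
  - Right_Superiorfrontal
  - Left_Precentral
  - Right_Precentral
thresholds: [1.0, 2.0]
z_max: 5.0
fit:
  k_range: [2, 3]
  n_folds: 3
  n_starts: 2
  n_iter_mcmc: 2000
predict:
  features: clinical
  n_folds: 5
  fixed_kernel: linear
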