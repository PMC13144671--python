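# Every pipeline default, surfaced in one place. Values shown are the
# built-in defaults; delete anything you do not want to override.

seed: 0

# --- methylation markers ---------------------------------------------------
min_cov: 3.0          # mean healthy coverage threshold per CpG
coverage_agg: mean    # or "all": every healthy sample must reach min_cov
pct: 10.0             # status percentile (bottom/top deciles)
beta_cut: 0.5         # beta threshold conjoined with the percentile rule
min_cpg: 3            # minimum CpGs per region
fdr: 0.05             # BH threshold for differential regions
blacklist_path: null  # optional BED of intervals to exclude
max_fallback_regions: 200

# --- copy number -----------------------------------------------------------
alpha_pct: 5.0        # healthy prevalence bound (exclusion + marker rule)
beta_pct: 20.0        # minimum cancer-type prevalence for a marker
k_sigma: 2.0          # alteration call threshold in healthy sigmas
include_losses: true

# --- fragmentomics ---------------------------------------------------------
fsd_lo: 80
fsd_hi: 220
fsd_width: 5

# --- classifiers -----------------------------------------------------------
candidates: [logreg, rf, gboost, svm_linear]
folds: 4

# --- ensemble --------------------------------------------------------------
target_specificity: 0.95
too_delta: 0.07       # top1-top2 ambiguity threshold ("in between")
logit_eps: 1.0e-6
uniform_too_weights: false
healthy_min_age: 50.0 # healthy training restricted to >= this age

# --- synthetic cohort ------------------------------------------------------
sim:
  n_healthy: 50
  n_per_cancer_per_stage: 5
  n_cpg_sites: 20000
  n_cnv_bins: 200
  n_fsr_windows: 100
  coverage_mean: 30.0
  dmr_effect: 0.6
  cnv_segment_effect: 0.6
  frag_healthy_mode: 166
  frag_tumor_mode: 145
  chip_rate: 0.0
  seed: 0
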