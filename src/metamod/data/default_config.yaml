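# Default pipeline configuration.
#
# The simulate block mimics a non-small-cell lung cancer registry cohort
# (3298 metastatic / 4012 early-primary) at quarter scale so test runs
# stay fast; per-gene carrier probabilities span the 0.5–15% range seen
# in targeted panel sequencing.
seed: 0
log_level: INFO

paths:
  mutations: mutations.tsv
  clinical: clinical.tsv
  drivers: drivers.tsv
  survival: survival.tsv
  out_dir: metamod_out

filters:
  assay_allowlist: null   # e.g. [IMPACT341, IMPACT410, IMPACT468]

enrichment:
  min_met_samples: 5
  max_module_size: 3
  alpha: 0.05
  alpha_strict: 0.01

survival_genes: [PTPRT]

simulate:
  cancer_type: NSCLC
  n_metastatic: 824
  n_early: 1003
  # genes: omit to use the built-in panel (TP53 0.15 ... MET 0.005)
  enriched_modules:
    - genes: [PTPRT]
      odds_ratio: 2.5
  msi_h_fraction: 0.04
  msi_inflation: 5.0
  stage_distribution: {I: 0.35, II: 0.30, III: 0.20, IV: 0.15}
  met_tissue_fraction: 0.7
  silent_rate: 0.25
  hazard_rate: 0.02
  hazard_ratio: 2.0
  censor_horizon: 120.0
  assay_id: SIMPANEL-1
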