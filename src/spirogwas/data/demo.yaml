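# Demonstration pipeline configuration: a 2,000-subject, 5,000-SNP synthetic
# cohort with two planted shared-effect SNPs, every stage enabled at a scale
# that runs in minutes on a single CPU.
sim:
  n_subjects: 2000
  n_snps: 5000
  maf_range: [0.05, 0.5]
  stratum_mix: 0.511
  missing_genotype_rate: 0.01
  spirometry_noise: 1.0
  causal_snps:
    - snp_index: 100
      log_odds_per_allele: 0.55
    - snp_index: 2500
      log_odds_per_allele: -0.45
  seed: 1
qc:
  min_call_rate: 0.95
  min_maf: 0.01
  min_hwe_p: 1.0e-4
overlap_thresholds: [0.05, 0.01, 1.0e-3, 1.0e-4, 1.0e-5, 1.0e-6]
add_bonferroni_threshold: true
expansion_factors: [2]
null_overlap_replicates: 3
null_overlap_thresholds: [1.0e-3, 1.0e-4]
null_overlap_stratum: never
candidate_threshold: 1.0e-3
min_candidates: 2
n_validation_cohorts: 2
validation_n_subjects: 1500
eqtl_noise_sd: 1.0
eqtl_slope: 0.4
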