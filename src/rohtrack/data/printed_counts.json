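{
  "description": "Published cohort-level summary counts for the NCI-60 vs HapMap CEU trio comparison on the Affymetrix 500K array; inputs to desk-scale recomputation of ratios, fold changes and resampling proportions.",
  "n_fras_total": 111,
  "n_mirna_autosomal": 955,
  "mirna_within_1mb_of_fra": 63,
  "mirna_within_5mb_of_fra": 334,
  "prior_study_mirna_total": 186,
  "prior_study_mirna_within_1mb": 13,
  "mean_rohf_nci60": 0.32,
  "mean_rohf_hapmap": 0.03,
  "mean_rohf_adult_pct": 3.42,
  "mean_rohf_young_pct": 3.36,
  "resampling": {
    "n_iter": 1000,
    "subsample_size": 30,
    "hmm": {"n_positive": 662, "n_significant": 747, "n_significant_positive": 552},
    "window": {"n_positive": 833, "n_significant": 743, "n_significant_positive": 686}
  },
  "n_loci_genome_wide": 489441,
  "alpha": 0.05
}
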