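{
  "out_dir": "results/pipeline_demo",
  "caller": "both",
  "seed": 1,
  "simulate": {
    "n_chromosomes": 3,
    "snps_per_chromosome": 1000,
    "chromosome_length_bp": 30000000,
    "n_samples_tumor": 30,
    "n_samples_control": 45,
    "het_rate": 0.3,
    "error_rate": 0.01,
    "nocall_rate_tumor": 0.042,
    "nocall_rate_control": 0.005,
    "n_hotspots": 3,
    "hotspot_freq_tumor": 0.5,
    "hotspot_freq_control": 0.1,
    "hotspot_length_bp": 4000000,
    "private_roh_rate": 0.3,
    "private_roh_mean_len_bp": 2500000
  },
  "hmm": {"het_rate": 0.3, "error_rate": 0.01},
  "window": {
    "window_snps": 25,
    "max_het_per_window": 1,
    "max_missing_per_window": 2,
    "hit_fraction": 0.05,
    "min_snps_per_segment": 50,
    "min_length_kb": 1000,
    "max_gap_kb": 1000,
    "max_density_kb_per_snp": 50
  },
  "resampling": {"n_iter": 100, "subsample_size": 15, "alpha": 0.05, "paired": true},
  "n_fras": 5,
  "n_mirna": 40
}
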