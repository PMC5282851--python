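{
  "n_samples": 26,
  "total_artifacts": 3180.0,
  "artifact_slope": 1.0,
  "artifact_dispersion": 3.5,
  "high_af_trigger": 1.5,
  "high_af_range": [0.09, 0.20],
  "coverage_mean_depth": 2000.0,
  "seed": 0
}
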