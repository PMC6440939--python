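{
  "comment": "Reference means and standard deviations used to standardize quality metrics. These are this package's own synthetic reference constants chosen to represent a typical well-refined experimental structure; they are not compiled from any published validation set.",
  "rama_outlier_fraction": {"mu": 0.01, "sigma": 0.02},
  "clash_rate_per_1000_atoms": {"mu": 10.0, "sigma": 8.0}
}
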