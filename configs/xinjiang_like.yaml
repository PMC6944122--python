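# Full-pipeline configuration. With no input files listed, every table is
# synthesized from the seeded default scenario; point the *_file keys at
# your own CSVs (see README for schemas) to run on real data.
seed: 0
out_dir: outputs
delta_coef: 0.52        # effective-precipitation coefficient
clamp_cwr: true         # clamp negative monthly CWR at zero
angstrom_as: 0.25       # sunshine-to-radiation regression intercept
angstrom_bs: 0.50       # sunshine-to-radiation regression slope
albedo: 0.23            # reference-surface albedo
balanced_band_m3: 1.0e7 # |dW| below this counts as balanced
scarcity_threshold_m3: -1.0e9  # dW at or below this is serious scarcity
thiessen_metric: euclidean
actuals_bias: -0.34     # synthetic withdrawals relative to requirement
actuals_noise_sd_m3: 0.0
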