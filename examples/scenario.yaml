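# Two-pass demo: simulate a pika-like cohort with mouse controls, fit with
# all calibration coefficients at 1, derive averaged coefficients from three
# seeded index animals (one per site), refit, and report.
scenario:
  seed: 11
  consumer_noise_cv: 0.02
  n_controls: 5
out_dir: demo_run
index_seed: 7
step: 0.01
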