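# Full-pipeline demo: a synthetic 31-day month of 6 night-peaking terms.
synthetic:
  n_days: 31
  baseline: 50.0
  diurnal_amplitude: 15.0
  acrophase: 2.0
  trend_amplitude: 20.0
  trend_period: 72.0
  noise_hf_amplitude: 3.0
  noise_hf_period: 2.0
  white_sd: 5.0
band:
  min_period: 4.0
  max_period: 32.0
alpha: 0.05
block_unit: hour
out_dir: demo_results
seed: 1
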