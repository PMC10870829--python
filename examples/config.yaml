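# Example run configuration for `coalburden all --config examples/config.yaml`.
# Any omitted key falls back to the package default.
world:
  n_egus: 25
  n_years: 12
  grid_size: 20
  start_year: 1999
  beta_true: 0.012422519998277177   # ln(1.0125) per ug/m3
  emissions_decline: 0.92
  scrubber_effect: 0.25
  wind_mean: [0.35, 0.05]
  diffusion_sd: 0.6
  parcel_lifetime: 4.0
  n_parcels: 500
  releases_per_year: 6
  seed: 1
  confounding:
    enabled: false
    gamma: 0.0
    noise_sd: 0.3
training_year: 1999
copollutant_sets: [[no2], [residual_pm25]]
rr_comparisons:
  - {label: medicare_total_pm25, rr: 1.0060, per_ug: 1.0, ci: [1.0053, 1.0067]}
  - {label: general_total_pm25, rr: 1.016, per_ug: 10.0, ci: [1.014, 1.018]}
fd_mode: consecutive
fd_scale: rate
emissions_quantile: 0.5
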