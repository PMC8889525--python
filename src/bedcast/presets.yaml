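# Synthetic census presets.  Values are SyntheticConfig fields; see
# bedcast.synthetic for units and semantics.

tertiary_350:
  n_days: 1095
  base_level: 340.0
  weekday_profile: [5.0, 12.0, 15.0, 12.0, 0.0, -22.0, -25.0]
  ar_coefficients: [0.5, 0.2]
  noise_sd: 8.0
  covariate_loadings:
    medicine_census: [0.45, 4.0]
    surgical_census: [0.25, 3.0]
    midnight_census: [0.95, 3.0]
  start_date: "2015-01-01"

regime_switching:
  n_days: 1500
  base_level: 340.0
  weekday_profile: [5.0, 12.0, 15.0, 12.0, 0.0, -22.0, -25.0]
  ar_coefficients: [0.5, 0.2]
  noise_sd: 8.0
  regimes:
    - {shift: 0.0, mean_duration: 60.0, profile_gain: 1.0}
    - {shift: 60.0, mean_duration: 60.0, profile_gain: 2.5}
  covariate_loadings:
    medicine_census: [0.45, 4.0]
    surgical_census: [0.25, 3.0]
    midnight_census: [0.95, 3.0]
  start_date: "2015-01-01"
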