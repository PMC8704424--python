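# Population calibrated to the measured charge thresholds:
# single-pulse medians 0.83 / 1.8 / 3.6 nC and responsive fractions
# 0.47 / 1.0 / 1.0 for 10 / 20 / 30 um electrodes; pulse-train thresholds
# 0.46 / 1.6 / 2.4 nC enter via the train threshold factors.
# CIC limits are exact arithmetic at 3.3 mC/cm2. Count parameters are the
# dynamic-range calibration shared with the companion dynamic-range preset.
latency:
  short_mean_s: 0.010
  short_shape: 2.0
  long_range_s: [0.1, 0.4]
  short_weight: 0.6
max_distance_um: 25.0
diameters:
  - diameter_um: 10.0
    p_resp: 0.47
    threshold_median_nC: 0.83
    threshold_dispersion: 0.35
    slope_frac: 0.1
    count_at_threshold: 2.0
    spont_rate_mean_hz: 0.15
    count_max_median: 2.307
    train_threshold_factor: 0.5542
    train_gain_factor: 1.584
    cic_limit_nC: 2.5918
  - diameter_um: 20.0
    p_resp: 1.0
    threshold_median_nC: 1.8
    threshold_dispersion: 0.35
    slope_frac: 0.1
    count_at_threshold: 2.0
    spont_rate_mean_hz: 0.15
    count_max_median: 3.971
    train_threshold_factor: 0.8889
    train_gain_factor: 1.326
    cic_limit_nC: 10.367
  - diameter_um: 30.0
    p_resp: 1.0
    threshold_median_nC: 3.6
    threshold_dispersion: 0.35
    slope_frac: 0.1
    count_at_threshold: 2.0
    spont_rate_mean_hz: 0.15
    count_max_median: 5.898
    train_threshold_factor: 0.6667
    train_gain_factor: 1.285
    cic_limit_nC: 23.326
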