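# Simulation scenario 2: the two Gaussian markers only; both groups share
# identical means and random-effects covariance, and differ solely in the
# residual (measurement-error) standard deviations.
# Time is in months; visit days are converted with months = days * 12/365.25.
name: scenario2
group_sizes: [200, 50]
visit_windows_days: [[170.0, 200.0], [350.0, 390.0], [710.0, 770.0]]
markers:
  - {name: albumin, family: gaussian, random_intercept: true, random_slope: true, fixed_slope: false}
  - {name: lbili, family: gaussian, random_intercept: true, random_slope: true, fixed_slope: false}
groups:
  - means:
      albumin: {intercept: 3.00, slope: 0.00}
      lbili: {intercept: 1.00, slope: 0.00}
    residual_sd: {albumin: 3.14e-1, lbili: 3.95e-1}
    random_effect_sd:
      albumin: {intercept: 6.50e-2, slope: 7.76e-3}
      lbili: {intercept: 1.12e-2, slope: 1.49e-2}
    correlations:
      - [albumin:intercept, albumin:slope, -6.46e-2]
      - [albumin:intercept, lbili:intercept, -1.97e-1]
      - [albumin:intercept, lbili:slope, 2.11e-1]
      - [albumin:slope, lbili:intercept, 1.57e-3]
      - [albumin:slope, lbili:slope, -2.33e-1]
      - [lbili:intercept, lbili:slope, -1.75e-1]
  - means:
      albumin: {intercept: 3.00, slope: 0.00}
      lbili: {intercept: 1.00, slope: 0.00}
    residual_sd: {albumin: 1.59e-1, lbili: 1.69e-1}
    random_effect_sd:
      albumin: {intercept: 6.50e-2, slope: 7.76e-3}
      lbili: {intercept: 1.12e-2, slope: 1.49e-2}
    correlations:
      - [albumin:intercept, albumin:slope, -6.46e-2]
      - [albumin:intercept, lbili:intercept, -1.97e-1]
      - [albumin:intercept, lbili:slope, 2.11e-1]
      - [albumin:slope, lbili:intercept, 1.57e-3]
      - [albumin:slope, lbili:slope, -2.33e-1]
      - [lbili:intercept, lbili:slope, -1.75e-1]
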