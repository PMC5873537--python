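# Simulation scenario 1: four markers of mixed type; the two prognostic
# groups differ in their mean profiles (fixed effects / random-effect means)
# while sharing a common random-effects covariance matrix.
# Time is in months; visit days are converted with months = days * 12/365.25.
name: scenario1
group_sizes: [200, 50]
visit_windows_days: [[170.0, 200.0], [350.0, 390.0], [710.0, 770.0]]
markers:
  - {name: albumin, family: gaussian, random_intercept: true, random_slope: true, fixed_slope: false}
  - {name: lbili, family: gaussian, random_intercept: true, random_slope: true, fixed_slope: false}
  - {name: platelet, family: poisson, random_intercept: true, random_slope: true, fixed_slope: false}
  - {name: bvm, family: bernoulli, random_intercept: true, random_slope: false, fixed_slope: true}
groups:
  - means:
      albumin: {intercept: 3.69, slope: -6.83e-3}
      lbili: {intercept: 2.13e-2, slope: 9.94e-3}
      platelet: {intercept: 5.54, slope: -4.29e-3}
      bvm: {intercept: -2.54}
    fixed:
      bvm: {slope: 1.46e-2}
    residual_sd: {albumin: 3.18e-1, lbili: 3.38e-1}
    random_effect_sd:
      albumin: {intercept: 2.64e-1, slope: 7.76e-3}
      lbili: {intercept: 8.45e-1, slope: 1.49e-2}
      platelet: {intercept: 3.45e-1, slope: 1.51e-2}
      bvm: {intercept: 1.88}
    correlations:
      - [albumin:intercept, albumin:slope, -6.46e-2]
      - [albumin:intercept, lbili:intercept, -1.97e-1]
      - [albumin:intercept, lbili:slope, 2.11e-1]
      - [albumin:intercept, platelet:intercept, 1.91e-1]
      - [albumin:intercept, platelet:slope, 1.09e-1]
      - [albumin:intercept, bvm:intercept, -3.48e-1]
      - [albumin:slope, lbili:intercept, 1.57e-3]
      - [albumin:slope, lbili:slope, -2.33e-1]
      - [albumin:slope, platelet:intercept, -2.57e-1]
      - [albumin:slope, platelet:slope, -2.60e-1]
      - [albumin:slope, bvm:intercept, 2.27e-1]
      - [lbili:intercept, lbili:slope, -1.75e-1]
      - [lbili:intercept, platelet:intercept, 2.47e-1]
      - [lbili:intercept, platelet:slope, -1.87e-1]
      - [lbili:intercept, bvm:intercept, 2.70e-1]
      - [lbili:slope, platelet:intercept, -1.69e-1]
      - [lbili:slope, platelet:slope, 1.25e-1]
      - [lbili:slope, bvm:intercept, 8.13e-3]
      - [platelet:intercept, platelet:slope, 6.14e-2]
      - [platelet:intercept, bvm:intercept, -2.48e-1]
      - [platelet:slope, bvm:intercept, -8.03e-2]
  - means:
      albumin: {intercept: 3.39, slope: -1.44e-2}
      lbili: {intercept: 1.23, slope: 2.38e-2}
      platelet: {intercept: 5.46, slope: -1.14e-2}
      bvm: {intercept: -6.81e-1}
    fixed:
      bvm: {slope: 4.81e-2}
    residual_sd: {albumin: 3.14e-1, lbili: 3.96e-1}
    random_effect_sd:
      albumin: {intercept: 2.64e-1, slope: 7.76e-3}
      lbili: {intercept: 8.45e-1, slope: 1.49e-2}
      platelet: {intercept: 3.45e-1, slope: 1.51e-2}
      bvm: {intercept: 1.88}
    correlations:
      - [albumin:intercept, albumin:slope, -6.46e-2]
      - [albumin:intercept, lbili:intercept, -1.97e-1]
      - [albumin:intercept, lbili:slope, 2.11e-1]
      - [albumin:intercept, platelet:intercept, 1.91e-1]
      - [albumin:intercept, platelet:slope, 1.09e-1]
      - [albumin:intercept, bvm:intercept, -3.48e-1]
      - [albumin:slope, lbili:intercept, 1.57e-3]
      - [albumin:slope, lbili:slope, -2.33e-1]
      - [albumin:slope, platelet:intercept, -2.57e-1]
      - [albumin:slope, platelet:slope, -2.60e-1]
      - [albumin:slope, bvm:intercept, 2.27e-1]
      - [lbili:intercept, lbili:slope, -1.75e-1]
      - [lbili:intercept, platelet:intercept, 2.47e-1]
      - [lbili:intercept, platelet:slope, -1.87e-1]
      - [lbili:intercept, bvm:intercept, 2.70e-1]
      - [lbili:slope, platelet:intercept, -1.69e-1]
      - [lbili:slope, platelet:slope, 1.25e-1]
      - [lbili:slope, bvm:intercept, 8.13e-3]
      - [platelet:intercept, platelet:slope, 6.14e-2]
      - [platelet:intercept, bvm:intercept, -2.48e-1]
      - [platelet:slope, bvm:intercept, -8.03e-2]
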