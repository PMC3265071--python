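# Shipped default coefficients for the estrogen-mediated breast-cancer risk
# model.  Concentrations in mol/L, BMI in kg/m^2, logs natural.
model:
  # Postmenopausal non-HRT free estradiol: E2F = exp(slope*BMI + intercept)
  postmeno_e2f: {slope: 0.068847, intercept: -29.984}
  # Premenopausal follicular free estradiol (decreasing in BMI)
  premeno_e2f: {slope: -0.039851, intercept: -24.906}
  # Ratio of free estradiol, current ERT users vs non-users (dimensionless)
  ert_ratio: {slope: -0.023098, intercept: 1.2617}
  # Relative risk per doubling of free estradiol
  rr_doubling_postmeno: 1.50
  rr_doubling_premeno: 1.7018
  # Saturation cap, mol/L (postmenopausal only; the printed operative constant,
  # equal to the non-user concentration at BMI 30 to 3 s.f.).  Set
  # saturation_cap: computed to use exp(slope*30 + intercept) instead, or
  # null to disable.
  saturation_cap: 7.50e-13
  reference_bmi: 23.0

# Synthetic stand-in for the BMI distribution of US postmenopausal-age women:
# lognormal fitted to approximate quartiles 24 / 27.5 / 31.5 kg/m^2
# (mu = ln 27.5, sigma = ln(31.5/24) / (2 * 0.67449)), discretized on a
# 0.1 kg/m^2 grid over [15, 60].
bmi_distribution:
  family: lognormal
  mu: 3.3141860046725258
  sigma: 0.20158476469099215
  low: 15.0
  high: 60.0
  step: 0.1
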