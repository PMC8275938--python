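# Default brain-injury risk curves.
#
# SYNTHETIC APPROXIMATIONS: the literature curves these stand in for are not
# parameterized in any packaged source, so the entries below are plausible
# monotone curves on the published criterion scales. They are suitable for
# demonstrating the risk-report pipeline, NOT for quantitative injury
# prediction; supply your own curve file for real analyses.
- criterion: CSDM_0.15
  injury_type: DAI
  form: logistic
  params: {intercept: -3.0, slope: 5.0}
- criterion: CSDM_0.25
  injury_type: DAI
  form: logistic
  params: {intercept: -2.5, slope: 5.0}
- criterion: MPS
  injury_type: DAI
  form: weibull
  params: {scale: 1.0, shape: 2.8}
- criterion: DDM
  injury_type: contusion
  form: logistic
  params: {intercept: -4.0, slope: 12.0}
- criterion: MPS
  injury_type: contusion
  form: weibull
  params: {scale: 1.2, shape: 2.5}
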