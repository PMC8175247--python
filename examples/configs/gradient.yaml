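# 25 studies along an ambient-temperature gradient with a linearly
# temperature-dependent treatment effect, followed by the conditional
# (weighted meta-regression) analysis.
seed: 5
task: gradient
norms:
  - genotype: g1
    shape: linear
    params: {intercept: 0.0, slope: 1.0}
environment:
  family: uniform
  params: {lo: 18.0, hi: 30.0}
gradient:
  n_studies: 25
  x_range: [18.0, 30.0]
  delta0: -4.0
  delta1: 0.25
  se_per_study: 0.3
  n_per_arm: 10
output:
  dir: replinorm_out/gradient
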