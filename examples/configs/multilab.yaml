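# Heterogenized 20-lab experiment with an environment-dependent effect:
# simulate per-animal data, summarize per lab, estimate the G-by-E variance
# component and produce RLM-adjusted contrasts.
seed: 3
task: multilab
norms:
  - genotype: g1
    shape: linear
    params: {intercept: 10.0, slope: 0.3}
    domain: [10.0, 34.0]
environment:
  family: gaussian
  params: {mu: 22.0, sigma: 2.0}
design:
  n_labs: 20
  n_per_arm: 12
  genotypes: [g1]
  standardization: heterogenized
  within_noise_sd: 1.0
  small_effect_sd: 0.5
  delta0: -3.0
  delta1: 0.2
criteria:
  confidence: 0.95
output:
  dir: replinorm_out/multilab
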