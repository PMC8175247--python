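# Coverage of the population-average treatment effect by classical vs
# Random-Lab-Model intervals when the effect depends on the lab environment.
seed: 9
task: coverage
norms:
  - genotype: g1
    shape: flat
    params: {value: 0.0}
environment:
  family: gaussian
  params: {mu: 0.0, sigma: 1.0}
design:
  n_labs: 1
  n_per_arm: 50
  genotypes: [g1]
  standardization: heterogenized
  within_noise_sd: 0.5
  delta0: 1.0
  delta1: 1.0
simulation:
  n_replicates: 2000
output:
  dir: replinorm_out/coverage
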