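# Methods

## Model

The package is built around three objects and the maps between them.

**Reaction norm.** A genotype-specific deterministic function `h` from an
environmental parameter value `x` to the expected trait value,
`E(y | x) = h(x)`, valid only on a stated closed interval. Evaluation
outside the domain is an error — never clamping or extrapolation — because
a norm measured over one environmental range says nothing about behaviour
outside it. Shipped functional forms: flat, linear, quadratic, logistic,
and tabulated with linear interpolation between knots; each carries a
`shape_tag` used to dispatch composition.

**Environment distribution.** A density `g(x)` with a seeded sampler.
Families: Gaussian, uniform, and tabulated (grid density renormalized by
trapezoid rule, sampled by inverse-CDF interpolation). The normalization
invariant (`∫g = 1` to 1e-6 by adaptive quadrature) is checked on the
support, truncating unbounded supports at mean ± 8 sd.

**Induced trait distribution.** `compose_distribution` computes the
distribution of `h(X)`, `X ~ g` — the pushforward of the environment
through the norm, i.e. the distribution of *expected* trait values, with
measurement noise added downstream by the simulator, not here. Closed
forms exist in exactly two cases: a flat norm gives a point mass at the
constant, and a linear norm `a + bx` with `X ~ N(µ, σ)` gives
`N(a + bµ, |b|σ)`. Everything else is Monte Carlo with a mandatory
explicit seed; requesting a closed form elsewhere raises, it never silently
falls back. General non-monotone norms would need fragile analytic
inversion for a density-level change of variables, which is why the
empirical representation is the default.

**Small-effect aggregation.** Once dominating factors are standardized or
modelled, the residual environmental influence is a sum of many
independent zero-mean factors; `clt_aggregate` samples that sum and
reports its central-limit Gaussian `N(0, √Σv_k)`. This is the package's
justification for modelling the between-lab baseline offset as Gaussian.
An empty ensemble degenerates to a point mass at zero with a logged
warning rather than an error.

## The simulator

One animal in lab *j*, genotype *g*, arm *a* ∈ {0, 1}:

    y = h_g(x_j) + u_j + a · (δ₀ + δ₁ · x_j) + ε,
    u_j ~ N(0, small_effect_sd),   ε ~ N(0, within_noise_sd) iid.

Defaults and units: `x` in environment units (the gradient examples use
ambient temperature in °C over 18–30 °C), traits in arbitrary trait units,
`within_noise_sd = 1` (per-animal residual), `small_effect_sd = 0`
(between-lab baseline aggregate, off unless studied), `δ₀`/`δ₁` the
treatment effect at `x = 0` and its slope per environment unit.
Standardized designs pin `x_j` at the environment mean for every lab;
heterogenized designs let each lab draw its own `x_j`.

The structural point the simulator encodes: the additive offsets
`h_g(x_j)` and `u_j` are shared by both arms of a lab and cancel in the
treatment-minus-control contrast. Between-lab variance of the *effect*
therefore comes only from environment-dependent effects (`δ₁ ≠ 0`) or from
genotype-specific norms — a G×E interaction — never from ad-hoc "lab noise
on effects". Small-effect factors act on the baseline only; an
environment-dependent effect is expressed through `δ₁`.

Randomness is hierarchical: the integer seed spawns one `SeedSequence`
child per lab; within a lab, draws occur in a fixed order (dominating
factor, small-effect aggregate, then per-animal noise by genotype, arm,
animal index). Identical seeds give byte-identical CSV exports.

`make_gradient_fixture` generates the canonical gradient collection:
25 studies by default, evenly spaced over the range (even spacing, not
random, so the sorted-gradient reading is reproducible), true effect
`δ₀ + δ₁·x_i`, observed effect Gaussian around it with sd `se_per_study`.
Its nominal `n_per_arm` (default 10) and `s2` are bookkeeping values
back-computed so `se = √(s2·(1/n₁+1/n₂))` stays internally consistent.

## Replication criteria

* **Naive**: success iff `ȳ₁ − z·SE₁ < ȳ₂ < ȳ₁ + z·SE₁`. Bounds are
  open: a replicate exactly on the bound fails. Only the original study's
  SE enters the interval, by construction; the replicate's own sampling
  noise therefore makes the criterion's long-run success rate
  `2Φ(z/√2) − 1` (≈ 0.834 at z = 1.96) even when both studies measure the
  same truth — a property the tests pin down rather than hide.
* **Shifted CI**: the same interval translated by
  `h(x₂) − h(x₁)`. Requires both covariates; a missing one raises an
  error pointing at the alternatives. With a flat norm the shift is zero
  and the criterion reduces exactly to the naive one.
* **Tail product**: for each study mean independently, the tail mass of
  the induced trait distribution on the side away from its first moment
  `M₁` (upper tail above `M₁`, lower below; a mean exactly at `M₁`
  contributes 0.5, the continuous limit of the rule). Success iff the
  product exceeds `L`. For a continuous symmetric unimodal distribution
  the product is maximal, 0.25, at `ȳ₁ = ȳ₂ = M₁`. No reference value
  for `L` exists; the default `L = 0.0025 = 0.05²` lets each study sit at
  its own two-sided 5% tail and is configurable everywhere. Empirical
  tails use the raw survival function with no smoothing, and fewer than
  1,000 draws is an error unless explicitly overridden — smoothing or
  silent small-sample tails would hide bias.
* **Conditional-effect regression**: inverse-variance weighted least
  squares of `mean_effect` on `x` (statsmodels WLS, weights `1/se²`);
  each study succeeds if its own `± z·se` band contains the predicted
  conditional value at its `x`. All-identical covariates raise a
  collinearity error.

`reproducibility_rate` wraps any pairwise criterion over a list of
(original, replicate) pairs and reports a Wilson score interval (good
small-n behaviour, and a fixed, documented choice).

## Random Lab Model

`rlm_se(s², n₁, n₂, s²_G×E) = √(s²(1/n₁ + 1/n₂) + 2·s²_G×E)`. The
`2·s²_G×E` term is read as the between-lab variance of the *contrast*
(one `s²_G×E` per arm-by-lab interaction), which makes the moment
estimator's division by two dimensionally consistent:

    ŝ²_G×E = max(0, (var(d_j) − mean(v_j)) / 2),

with `d_j` the per-lab contrasts and `v_j = se_j²` their sampling
variances; negative moment estimates truncate at zero (variance components
are nonnegative), and the raw components are returned for audit. With
several genotypes both moments are pooled across genotypes weighted by
degrees of freedom. At least three labs are required — the component is
not estimable from a single experiment. `s²` pools within lab across the
two arms.

Tests and intervals use a Gaussian reference rather than t: the penalty
term carries no degrees of freedom, so no t-distribution is defensible.
This is a documented limitation; at small `n` the *classical* column of a
coverage table undercovers by the usual t-vs-z amount, which is why the
shipped coverage experiments use 50 animals per arm.

`coverage_experiment` measures how often classical and RLM intervals cover
the population-average effect `δ₀ + δ₁·E[X]` over independent single-lab
studies. It generates replicates with a vectorized sampler implementing
the identical generative model as `simulate_multilab` (the lab offsets
cancel in the contrast, so only the effect and per-animal noise are
drawn). "Oracle" mode injects the simulator's true between-lab effect
variance, `s²_G×E = (δ₁·sd(X))²/2` (zero under standardization),
separating procedure error from estimator error.

## Problem sizes and numerical choices

Monte-Carlo composition defaults to 10⁵ draws (moments then carry ~0.3%
relative error); CLT demonstrations use 10⁴ samples and 200 factors;
variance-recovery experiments use 100 replicates of 50 labs × 20 per arm;
coverage experiments use 2,000 replicates. These sizes put simulation
error well inside the assertion tolerances while keeping any run in
seconds to a couple of minutes on one core. Gaussian tails come from
scipy's `sf`/`cdf`; tie-breaks at interval bounds are strict failures;
pdf normalization is accepted to 1e-6.

## What the simulator does and does not emulate

It emulates: one dominating environmental factor with a possibly
non-linear, genotype-specific norm (a skewed induced distribution arises
naturally from a non-linear norm — no separate estimator is provided for
that case); a Gaussian between-lab aggregate of small effects; effects
varying linearly along a gradient; balanced two-arm designs. It does not
emulate: cage/batch/rack structure below the lab level, longitudinal or
developmental environmental effects, unbalanced allocation, norm
*inference* from data, or multi-dimensional norm surfaces. Passing tests
therefore demonstrate the internal consistency of this variance structure,
not that any particular real trait follows it.

## Known limitations

* The Gaussian reference for RLM inference (no df accounting).
* The moment estimator assumes exchangeable labs and balanced designs;
  severely heteroscedastic `v_j` would call for a weighted variant.
* The tail-product criterion needs the induced trait distribution —
  in practice a known norm and environment distribution — which is rarely
  available outside simulation studies.
* The shifted-CI criterion uses only the original study's SE, as defined;
  it does not widen the acceptance region for replicate uncertainty.
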