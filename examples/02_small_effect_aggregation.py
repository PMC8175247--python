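"""Aggregate many small-effect environmental factors into their Gaussian limit.

After dominating environmental factors are standardized away, the residual
influence on the trait is the sum of many independent small effects.  By
the central limit theorem that sum behaves like a Gaussian whose variance
is the sum of the factor variances — which is why a between-lab random
effect is usually modelled as Gaussian.
"""

from scipy import stats

import replinorm as rn

ensemble = rn.SmallEffectEnsemble.iid_uniform(count=200, half_width=0.05)
samples, (mu, sd) = rn.clt_aggregate(ensemble, n_samples=10_000, seed=7)

print(f"{ensemble.count} factors, each Uniform(-0.05, 0.05)")
print(f"limiting Gaussian: N({mu}, {sd:.4f})  "
      f"(sd = sqrt(200 * 0.1^2 / 12))")
print(f"sample sd of the aggregate: {samples.std(ddof=1):.4f}")
ks = stats.kstest(samples, "norm", args=(mu, sd))
print(f"KS test against the limit: p = {ks.pvalue:.3f} "
      "(large p: Gaussian limit not rejected)")
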