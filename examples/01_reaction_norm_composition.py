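"""Compose a reaction norm with an environment distribution.

A genotype's reaction norm h maps an environmental value (here, a
temperature-like parameter) to the expected trait value; when the
environment is random, the induced distribution of expected trait values is
the pushforward h(X).  For a linear norm and a Gaussian environment the
result is Gaussian in closed form; anything else is Monte Carlo.
"""

import replinorm as rn

norm = rn.linear_norm(intercept=1.0, slope=2.0, genotype_label="g1")
env = rn.gaussian_environment(mu=0.0, sigma=1.0)

closed = rn.compose_distribution(norm, env, method="closed_form")
mc = rn.compose_distribution(norm, env, method="monte_carlo",
                             n_samples=100_000, seed=42)

print(f"closed form:  N(mu={closed.mu:.3f}, sigma={closed.sigma:.3f})")
print(f"monte carlo:  mean={mc.m1:.3f}, sd={mc.sd:.3f}  (n={mc.sample_size})")
# The two agree: E[h(X)] = 1 + 2*E[X] = 1 and sd = |2|*sd(X) = 2.

curved = rn.quadratic_norm(0.0, 0.0, 1.0, genotype_label="g_curved")
pushed = rn.compose_distribution(curved, env, method="monte_carlo",
                                 n_samples=100_000, seed=43)
print(f"h(x)=x^2 pushforward: mean={pushed.m1:.3f} (E[X^2]=1 for N(0,1)),"
      f" sd={pushed.sd:.3f}")

# A flat norm collapses any environment to a single expected value.
flat = rn.compose_distribution(rn.flat_norm(5.0), env, method="closed_form")
print(f"flat norm: point mass at {flat.m1}, sd={flat.sd}")
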