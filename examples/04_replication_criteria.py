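"""Judge replication success three ways.

* naive: replicate mean inside the original study's CI;
* shifted CI: shift that interval by the expected trait displacement
  h(x2) - h(x1) when both studies' environments are known;
* tail product: when only the environment's *distribution* is known, score
  each mean by the tail mass of the induced trait distribution beyond it
  (taken away from the first moment M1) and require the product to exceed L.
"""

import replinorm as rn

norm = rn.linear_norm(0.0, 2.0, genotype_label="g1")

original = rn.StudyResult("lab_A", "g1", mean_effect=0.0, se=1.0,
                          n1=10, n2=10, x=0.0, s2=5.0)
replicate = rn.StudyResult("lab_B", "g1", mean_effect=2.0, se=1.0,
                           n1=10, n2=10, x=1.0, s2=5.0)

naive = rn.assess_naive(original, replicate, z=1.96)
print(f"naive:   success={naive.success}  interval={naive.interval}")
# 2.0 lies outside (-1.96, 1.96): judged a failed replication.

shifted = rn.assess_shifted(original, replicate, norm, z=1.96)
print(f"shifted: success={shifted.success}  shift={shifted.shift:.2f}  "
      f"interval=({shifted.interval[0]:.2f}, {shifted.interval[1]:.2f})")
# Knowing lab_B ran 1 environment unit warmer, the expected displacement
# h(1)-h(0)=2 moves the interval to (0.04, 3.96): the same replicate now
# counts as successful.

dist = rn.compose_distribution(norm, rn.gaussian_environment(0.0, 1.0),
                               method="closed_form")
tail = rn.assess_tail_product(0.5, 3.0, dist, L=0.0025)
print(f"tailprod: success={tail.success}  product={tail.product:.4f}  "
      f"(threshold L=0.0025)")
# Both means are plausible draws from the environmental ensemble when the
# product of their away-from-M1 tail masses exceeds L.
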