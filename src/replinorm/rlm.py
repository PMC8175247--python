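"""Random Lab Model (RLM) inference.

The RLM widens the standard error of a two-group contrast by a penalizing
genotype-by-environment (GxE) term,

    SE = sqrt( s2 * (1/n1 + 1/n2) + 2 * s2_gxe ),

where ``s2`` is the pooled within-group variance and ``2 * s2_gxe`` is the
expected between-lab variance of the contrast.  Trading power for realism,
this "adjusted yardstick" makes a single-lab confidence interval honest
about how much the effect would move in another laboratory.

``s2_gxe`` cannot be estimated from a single experiment; this module adds a
method-of-moments estimator for multi-lab data (variance of per-lab effects
minus their mean sampling variance, halved, truncated at zero) and a
coverage experiment quantifying what the adjustment buys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InsufficientReplicationError
from .norms import EnvironmentDistribution
from .simulate import MultiLabDataset, StudyDesign, StudyResult, summarize_labs

__all__ = [
    "RLMEstimate",
    "rlm_se",
    "rlm_contrast",
    "estimate_gxe_variance",
    "coverage_experiment",
]


@dataclass(frozen=True)
class RLMEstimate:
    """A two-group contrast with its GxE-adjusted uncertainty."""

    effect: float
    s2: float
    n1: int
    n2: int
    s2_gxe: float
    se_adjusted: float
    ci: tuple[float, float]
    statistic: float
    p_value: float
    confidence: float

    @property
    def se_classical(self) -> float:
        return math.sqrt(self.s2 * (1.0 / self.n1 + 1.0 / self.n2))

    def to_dict(self) -> dict:
        return {
            "effect": self.effect, "s2": self.s2, "n1": self.n1, "n2": self.n2,
            "s2_gxe": self.s2_gxe, "se_adjusted": self.se_adjusted,
            "ci_lower": self.ci[0], "ci_upper": self.ci[1],
            "statistic": self.statistic, "p_value": self.p_value,
            "confidence": self.confidence,
        }


def rlm_se(s2: float, n1: int, n2: int, s2_gxe: float) -> float:
    """GxE-penalized standard error ``sqrt(s2*(1/n1+1/n2) + 2*s2_gxe)``.

    Reduces to the classical pooled-variance SE when ``s2_gxe = 0`` and is
    strictly increasing in ``s2_gxe``.
    """
    if s2 < 0 or s2_gxe < 0:
        raise ValueError("variances must be nonnegative")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per arm")
    return math.sqrt(s2 * (1.0 / n1 + 1.0 / n2) + 2.0 * s2_gxe)


def rlm_contrast(study: StudyResult, s2_gxe: float,
                 confidence: float = 0.95) -> RLMEstimate:
    """RLM-adjusted estimate and confidence interval for one study's contrast.

    Uses a Gaussian reference distribution: the penalty term carries no
    degrees of freedom, so a t reference is not defensible.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    if study.s2 is None:
        raise ValueError("study carries no pooled variance s2")
    se = rlm_se(study.s2, study.n1, study.n2, s2_gxe)
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    effect = study.mean_effect
    statistic = effect / se
    p = 2.0 * float(stats.norm.sf(abs(statistic)))
    return RLMEstimate(
        effect=effect, s2=study.s2, n1=study.n1, n2=study.n2, s2_gxe=s2_gxe,
        se_adjusted=se, ci=(effect - z * se, effect + z * se),
        statistic=statistic, p_value=p, confidence=confidence,
    )


def estimate_gxe_variance(data: MultiLabDataset) -> tuple[float, dict]:
    """Method-of-moments estimate of ``s2_gxe`` from multi-lab data.

    Per lab (and genotype) the contrast ``d_j`` and its sampling variance
    ``v_j = se_j^2`` are computed; the between-lab variance of the true
    effects is then ``var(d_j) - mean(v_j)``, and since the RLM
    parameterizes that quantity as ``2 * s2_gxe``,

        s2_gxe_hat = max(0, (var(d_j) - mean(v_j)) / 2).

    With several genotypes the two moments are pooled across genotypes
    (degrees-of-freedom weighted).  Returns the estimate and an audit dict
    with the raw components.
    """
    results = summarize_labs(data)
    by_genotype: dict[str, list[StudyResult]] = {}
    for r in results:
        by_genotype.setdefault(r.genotype_label, []).append(r)
    n_labs = min(len(v) for v in by_genotype.values())
    if n_labs < 3:
        raise InsufficientReplicationError(
            f"only {n_labs} labs; the GxE variance component cannot be "
            f"estimated from so few laboratories (never from a single "
            f"experiment) — need >= 3"
        )
    var_num = 0.0
    var_dof = 0
    v_sum = 0.0
    v_count = 0
    for rs in by_genotype.values():
        d = np.array([r.mean_effect for r in rs])
        v = np.array([r.se ** 2 for r in rs])
        var_num += d.var(ddof=1) * (len(d) - 1)
        var_dof += len(d) - 1
        v_sum += v.sum()
        v_count += len(v)
    var_d = var_num / var_dof
    mean_v = v_sum / v_count
    estimate = max(0.0, (var_d - mean_v) / 2.0)
    components = {
        "var_between_lab_effects": float(var_d),
        "mean_sampling_variance": float(mean_v),
        "n_labs": int(n_labs),
        "n_genotypes": len(by_genotype),
        "truncated": bool(var_d < mean_v),
    }
    return float(estimate), components


def _oracle_s2_gxe(design: StudyDesign, env: EnvironmentDistribution) -> float:
    """True between-lab contrast variance under the generative model, halved.

    The contrast in lab j is ``delta0 + delta1 * x_j`` plus sampling noise,
    so the between-lab variance of the true effect is ``delta1^2 * var(X)``
    (zero under standardization); the RLM books that as ``2 * s2_gxe``.
    """
    if design.standardization == "standardized" or design.delta1 == 0:
        return 0.0
    if env.sd is None:
        raise ValueError("oracle mode needs an environment with known sd")
    return (design.delta1 * env.sd) ** 2 / 2.0


def coverage_experiment(
    design: StudyDesign,
    env: EnvironmentDistribution,
    n_replicates: int,
    s2_gxe_used: float | str = "oracle",
    seed: int = 0,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Coverage of the population-average effect by classical vs RLM intervals.

    Simulates ``n_replicates`` independent single-lab two-arm studies from
    the same generative model as :func:`~replinorm.simulate.simulate_multilab`
    (vectorized over replicates; lab offsets cancel in the contrast) and
    records how often each procedure's interval covers the population-average
    true effect ``delta0 + delta1 * E[X]``.

    ``s2_gxe_used="oracle"`` injects the simulator's true between-lab effect
    variance, separating procedure error from estimator error.

    Returns a two-row table (procedures ``classical`` and ``rlm``) with
    empirical coverage and Wilson interval bounds.
    """
    if n_replicates < 100:
        raise ValueError("need n_replicates >= 100")
    if len(design.genotypes) != 1:
        raise ValueError("coverage_experiment expects a single-genotype design")
    if env.mean is None:
        raise ValueError("coverage target needs an environment with known mean")
    s2_gxe = _oracle_s2_gxe(design, env) if s2_gxe_used == "oracle" else float(s2_gxe_used)
    if s2_gxe < 0:
        raise ValueError("s2_gxe must be nonnegative")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = design.n_per_arm
    if design.standardization == "standardized":
        x = np.full(n_replicates, float(env.mean))
    else:
        x = env.sample(n_replicates, rng)
    # lab baseline h(x)+u cancels in the contrast; only the effect and the
    # per-animal noise matter
    true_effect = design.delta0 + design.delta1 * x
    eps_c = rng.normal(0.0, design.within_noise_sd, size=(n_replicates, n))
    eps_t = rng.normal(0.0, design.within_noise_sd, size=(n_replicates, n))
    d_hat = true_effect + eps_t.mean(axis=1) - eps_c.mean(axis=1)
    s2 = ((n - 1) * eps_t.var(axis=1, ddof=1) + (n - 1) * eps_c.var(axis=1, ddof=1)) / (2 * n - 2)

    target = design.delta0 + design.delta1 * float(env.mean)
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    se_classical = np.sqrt(s2 * (2.0 / n))
    se_rlm = np.sqrt(s2 * (2.0 / n) + 2.0 * s2_gxe)
    rows = []
    for procedure, se in (("classical", se_classical), ("rlm", se_rlm)):
        covered = int(np.sum(np.abs(d_hat - target) < z * se))
        lo, hi = proportion_confint(covered, n_replicates, alpha=1 - confidence,
                                    method="wilson")
        rows.append({
            "procedure": procedure,
            "coverage": covered / n_replicates,
            "wilson_lower": float(lo),
            "wilson_upper": float(hi),
            "n_replicates": n_replicates,
            "s2_gxe": s2_gxe,
            "nominal": confidence,
        })
    return pd.DataFrame(rows)
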