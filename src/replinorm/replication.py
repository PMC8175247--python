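"""Replication-success criteria and reproducibility rates.

Three ways to ask whether a replicate study reproduced an original one:

* **naive** — the replicate's mean falls inside the original study's
  confidence interval, ``ybar1 ± z*SE1`` (strict inequalities).
* **shifted CI** — when the reaction norm and both studies' environmental
  values are known, the original interval is first shifted by the expected
  displacement ``h(x2) - h(x1)`` before checking inclusion.  With a flat
  norm this reduces exactly to the naive criterion.
* **tail product** — when only the *distribution* of the environment is
  known, each study mean is scored by the tail mass of the induced trait
  distribution on the side away from its first moment M1; replication
  succeeds if the product of the two tail masses exceeds a threshold L.

A fourth, regression-based view treats a collection of studies with a
recorded environmental covariate: the conditional effect is estimated by
inverse-variance weighted least squares and each study is checked against
its own predicted conditional value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .errors import (
    CollinearityError,
    DegenerateSEError,
    MissingCovariateError,
    StructuralError,
)
from .norms import EmpiricalTrait, ReactionNorm, TraitDistribution, expected_shift
from .simulate import StudyResult

__all__ = [
    "ReplicationAssessment",
    "GradientRegressionResult",
    "assess_naive",
    "assess_shifted",
    "assess_tail_product",
    "reproducibility_rate",
    "conditional_effect_regression",
    "DEFAULT_Z",
    "DEFAULT_L",
]

# two-sided 95% by default; L = 0.05**2 lets each study sit at its two-sided
# 5% tail.  Both are configurable everywhere they appear.
DEFAULT_Z = 1.96
DEFAULT_L = 0.0025


@dataclass(frozen=True)
class ReplicationAssessment:
    """Outcome of one replication-success check."""

    criterion: str
    success: bool
    z: float | None = None
    L: float | None = None
    interval: tuple[float, float] | None = None
    product: float | None = None
    shift: float | None = None

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "success": bool(self.success),
            "z": self.z,
            "L": self.L,
            "interval": list(self.interval) if self.interval else None,
            "product": self.product,
            "shift": self.shift,
        }


def _require_positive_se(study: StudyResult) -> None:
    if not study.se > 0:
        raise DegenerateSEError("original study has nonpositive standard error")


def assess_naive(original: StudyResult, replicate: StudyResult,
                 z: float = DEFAULT_Z) -> ReplicationAssessment:
    """Replicate mean strictly inside the original's ``ybar1 ± z*SE1``."""
    if z <= 0:
        raise ValueError("z must be positive")
    _require_positive_se(original)
    lo = original.mean_effect - z * original.se
    hi = original.mean_effect + z * original.se
    success = lo < replicate.mean_effect < hi
    return ReplicationAssessment("naive", success, z=z, interval=(lo, hi))


def assess_shifted(original: StudyResult, replicate: StudyResult,
                   norm: ReactionNorm, z: float = DEFAULT_Z) -> ReplicationAssessment:
    """Known-environment criterion: shift the original CI by ``h(x2) - h(x1)``.

    Both studies must carry their dominating-factor value ``x``; the
    expected displacement along the reaction norm is added to the original
    interval before the strict inclusion check.
    """
    if z <= 0:
        raise ValueError("z must be positive")
    _require_positive_se(original)
    for label, study in (("original", original), ("replicate", replicate)):
        if not study.x_known:
            raise MissingCovariateError(
                f"{label} study has no environmental covariate; use "
                f"assess_naive or assess_tail_product instead"
            )
    shift = expected_shift(norm, original.x, replicate.x)
    lo = shift + original.mean_effect - z * original.se
    hi = shift + original.mean_effect + z * original.se
    success = lo < replicate.mean_effect < hi
    return ReplicationAssessment("shifted_ci", success, z=z,
                                 interval=(lo, hi), shift=shift)


def _tail_factor(y_bar: float, dist: TraitDistribution) -> float:
    m1 = dist.m1
    if y_bar > m1:
        return dist.tail(y_bar, "upper")
    if y_bar < m1:
        return dist.tail(y_bar, "lower")
    # exactly at the first moment: a continuous symmetric distribution puts
    # half its mass on either side
    return 0.5


def assess_tail_product(
    y1_bar: float,
    y2_bar: float,
    dist: TraitDistribution,
    L: float = DEFAULT_L,
    allow_small_sample: bool = False,
) -> ReplicationAssessment:
    """Known-distribution criterion: product of away-from-M1 tail masses > L.

    For each study mean independently, the tail of the induced trait
    distribution is taken on the side away from the first moment M1 (upper
    tail for a mean above M1, lower tail below; a mean exactly at M1
    contributes 0.5).  Success means the product exceeds ``L``: both means
    are then plausible draws from the environmental ensemble.

    Empirical trait distributions with fewer than 1,000 draws raise a
    precision error unless ``allow_small_sample=True``.
    """
    if not 0 < L < 1:
        raise ValueError("L must lie in (0, 1)")
    if not math.isfinite(dist.m1):
        raise ValueError("trait distribution has no finite first moment")
    if isinstance(dist, EmpiricalTrait) and not allow_small_sample:
        dist.require_precision(1000)
    product = _tail_factor(y1_bar, dist) * _tail_factor(y2_bar, dist)
    return ReplicationAssessment("tail_product", product > L, L=L, product=product)


def reproducibility_rate(
    pairs: Sequence[tuple[StudyResult, StudyResult]],
    criterion: str = "naive",
    z: float = DEFAULT_Z,
    L: float = DEFAULT_L,
    norm: ReactionNorm | None = None,
    dist: TraitDistribution | None = None,
    conf_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Fraction of (original, replicate) pairs judged successful.

    Returns the empirical rate with a Wilson score interval at
    ``conf_level``.
    """
    if len(pairs) == 0:
        raise StructuralError("need at least one (original, replicate) pair")
    successes = 0
    for original, replicate in pairs:
        if criterion == "naive":
            a = assess_naive(original, replicate, z=z)
        elif criterion == "shifted_ci":
            if norm is None:
                raise ValueError("shifted_ci criterion needs a reaction norm")
            a = assess_shifted(original, replicate, norm, z=z)
        elif criterion == "tail_product":
            if dist is None:
                raise ValueError("tail_product criterion needs a trait distribution")
            a = assess_tail_product(original.mean_effect, replicate.mean_effect,
                                    dist, L=L)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        successes += int(a.success)
    n = len(pairs)
    lo, hi = proportion_confint(successes, n, alpha=1 - conf_level, method="wilson")
    return successes / n, (float(lo), float(hi))


@dataclass(frozen=True)
class GradientRegressionResult:
    """Inverse-variance weighted regression of effect size on environment."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    predicted: np.ndarray
    success: np.ndarray  # per study: predicted value inside its z*se band
    z: float

    @property
    def success_rate(self) -> float:
        return float(np.mean(self.success))


def conditional_effect_regression(
    studies: Sequence[StudyResult],
    z: float = DEFAULT_Z,
) -> GradientRegressionResult:
    """Meta-regression of study effects on a recorded environmental covariate.

    Fits ``mean_effect ~ intercept + slope * x`` by weighted least squares
    with weights ``1/se^2``, then flags each study as consistent with the
    conditional effect if its own ``mean_effect ± z*se`` band contains the
    predicted value at its ``x``.
    """
    if len(studies) < 3:
        raise StructuralError("need at least 3 studies")
    for s in studies:
        if not s.x_known:
            raise MissingCovariateError(
                f"study ({s.lab_id}, {s.genotype_label}) has no covariate x"
            )
        _require_positive_se(s)
    x = np.array([s.x for s in studies], dtype=float)
    y = np.array([s.mean_effect for s in studies], dtype=float)
    se = np.array([s.se for s in studies], dtype=float)
    if np.ptp(x) == 0:
        raise CollinearityError(
            "all studies share the same environmental value; the gradient is "
            "undefined — use assess_naive instead"
        )
    X = sm.add_constant(x)
    fit = sm.WLS(y, X, weights=1.0 / se ** 2).fit()
    intercept, slope = fit.params
    predicted = intercept + slope * x
    success = np.abs(y - predicted) < z * se
    return GradientRegressionResult(
        slope=float(slope), intercept=float(intercept),
        slope_se=float(fit.bse[1]), intercept_se=float(fit.bse[0]),
        predicted=predicted, success=success, z=z,
    )
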