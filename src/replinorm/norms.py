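"""Reaction norms, environment distributions and induced trait distributions.

A reaction norm is a genotype-specific function ``h`` mapping an
environmental parameter value ``x`` (e.g. ambient temperature) to the
expected value of a phenotypic trait, ``E(y | x) = h(x)``.  When the
environmental parameter itself is random, with density ``g``, pushing the
environment distribution through the norm induces a distribution of
*expected* trait values.  This module represents all three objects and the
composition between them, plus the Gaussian aggregation of many independent
small-effect environmental factors.
"""

from __future__ import annotations

import csv
import logging
import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, stats

from .errors import DomainError, PrecisionError, UnsupportedMethodError

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionNorm",
    "flat_norm",
    "linear_norm",
    "quadratic_norm",
    "logistic_norm",
    "tabulated_norm",
    "EnvironmentDistribution",
    "gaussian_environment",
    "uniform_environment",
    "tabulated_environment",
    "TraitDistribution",
    "GaussianTrait",
    "PointMassTrait",
    "EmpiricalTrait",
    "SmallEffectEnsemble",
    "evaluate_norm",
    "compose_distribution",
    "expected_shift",
    "clt_aggregate",
]


# ---------------------------------------------------------------------------
# Reaction norms
# ---------------------------------------------------------------------------

_SHAPE_TAGS = frozenset({"flat", "linear", "monotone", "general"})


@dataclass(frozen=True)
class ReactionNorm:
    """A genotype-specific mapping from environment value to expected trait.

    Parameters
    ----------
    genotype_label : str
        Identifier of the genotype the norm belongs to.
    h : callable
        Deterministic mapping ``x -> E(y | x)``; must be finite on ``domain``
        and vectorize over numpy arrays.
    domain : (float, float)
        Closed interval of environmental values over which the norm is
        valid.  Evaluation outside it is an error, never an extrapolation:
        a norm is only meaningful over the environmental range it was
        defined (or measured) on.
    shape_tag : {"flat", "linear", "monotone", "general"}
        Dispatch tag for the composition method.
    params : dict
        Named parameters of the functional form (used by closed-form
        composition; empty for opaque user functions).
    """

    genotype_label: str
    h: Callable[[np.ndarray | float], np.ndarray | float]
    domain: tuple[float, float] = (-math.inf, math.inf)
    shape_tag: str = "general"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape_tag not in _SHAPE_TAGS:
            raise ValueError(f"unknown shape_tag {self.shape_tag!r}")
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError(f"empty domain [{lo}, {hi}]")

    def _check_domain(self, x) -> None:
        lo, hi = self.domain
        arr = np.asarray(x, dtype=float)
        if np.any(arr < lo) or np.any(arr > hi):
            bad = arr[(arr < lo) | (arr > hi)]
            offender = float(np.atleast_1d(bad)[0])
            raise DomainError(
                f"environmental value {offender} outside the valid range "
                f"[{lo}, {hi}] of norm {self.genotype_label!r}"
            )

    def __call__(self, x):
        self._check_domain(x)
        y = self.h(np.asarray(x, dtype=float) if np.ndim(x) else float(x))
        if not np.all(np.isfinite(y)):
            raise ValueError(
                f"norm {self.genotype_label!r} returned a non-finite value"
            )
        return y


def flat_norm(value: float, genotype_label: str = "g",
              domain: tuple[float, float] = (-math.inf, math.inf)) -> ReactionNorm:
    """Environment-insensitive norm: ``h(x) = value`` for every ``x``."""
    return ReactionNorm(
        genotype_label=genotype_label,
        h=lambda x: np.full_like(np.asarray(x, dtype=float), value) if np.ndim(x) else float(value),
        domain=domain,
        shape_tag="flat",
        params={"value": float(value)},
    )


def linear_norm(intercept: float, slope: float, genotype_label: str = "g",
                domain: tuple[float, float] = (-math.inf, math.inf)) -> ReactionNorm:
    """Linear norm ``h(x) = intercept + slope * x``."""
    return ReactionNorm(
        genotype_label=genotype_label,
        h=lambda x: intercept + slope * np.asarray(x, dtype=float) if np.ndim(x) else intercept + slope * x,
        domain=domain,
        shape_tag="flat" if slope == 0 else "linear",
        params={"intercept": float(intercept), "slope": float(slope)},
    )


def quadratic_norm(a: float, b: float, c: float, genotype_label: str = "g",
                   domain: tuple[float, float] = (-math.inf, math.inf)) -> ReactionNorm:
    """Quadratic norm ``h(x) = a + b*x + c*x**2``."""
    def h(x):
        x = np.asarray(x, dtype=float) if np.ndim(x) else x
        return a + b * x + c * x ** 2

    return ReactionNorm(genotype_label, h, domain, "general",
                        {"a": float(a), "b": float(b), "c": float(c)})


def logistic_norm(lower: float, upper: float, midpoint: float, scale: float,
                  genotype_label: str = "g",
                  domain: tuple[float, float] = (-math.inf, math.inf)) -> ReactionNorm:
    """Sigmoidal norm rising from ``lower`` to ``upper`` around ``midpoint``.

    ``h(x) = lower + (upper - lower) / (1 + exp(-(x - midpoint)/scale))``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")

    def h(x):
        x = np.asarray(x, dtype=float) if np.ndim(x) else x
        return lower + (upper - lower) * stats.logistic.cdf(x, loc=midpoint, scale=scale)

    return ReactionNorm(genotype_label, h, domain, "monotone",
                        {"lower": lower, "upper": upper,
                         "midpoint": midpoint, "scale": scale})


def tabulated_norm(x: Sequence[float], y: Sequence[float],
                   genotype_label: str = "g") -> ReactionNorm:
    """Norm given as (x, h(x)) pairs, linearly interpolated between knots.

    The domain is the tabulated range; evaluation outside it raises
    :class:`~replinorm.errors.DomainError` rather than clamping or
    extrapolating.
    """
    xs = np.asarray(x, dtype=float)
    ys = np.asarray(y, dtype=float)
    if xs.ndim != 1 or xs.shape != ys.shape or xs.size < 2:
        raise ValueError("need two equal-length 1-d arrays with >= 2 points")
    order = np.argsort(xs)
    xs, ys = xs[order], ys[order]
    if np.any(np.diff(xs) <= 0):
        raise ValueError("tabulated x values must be distinct")

    def h(q):
        return np.interp(q, xs, ys)

    return ReactionNorm(genotype_label, h, (float(xs[0]), float(xs[-1])),
                        "general", {"x": xs.tolist(), "y": ys.tolist()})


def norm_from_csv(path: str | Path, genotype_label: str = "g") -> ReactionNorm:
    """Read a tabulated norm from a two-column CSV (x, value) with header."""
    xs, ys = _read_two_column_csv(path)
    return tabulated_norm(xs, ys, genotype_label=genotype_label)


def _read_two_column_csv(path: str | Path) -> tuple[list[float], list[float]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise ValueError(f"{path}: expected a two-column CSV with header")
        xs, ys = [], []
        for row in reader:
            if not row:
                continue
            xs.append(float(row[0]))
            ys.append(float(row[1]))
    return xs, ys


# ---------------------------------------------------------------------------
# Environment distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvironmentDistribution:
    """Distribution ``g`` of the environmental parameter ``X``.

    Wraps a density, a seeded sampler and support information.  Built via
    :func:`gaussian_environment`, :func:`uniform_environment` or
    :func:`tabulated_environment`.
    """

    family: str
    pdf: Callable[[np.ndarray | float], np.ndarray | float]
    sampler: Callable[[np.random.Generator, int], np.ndarray]
    support: tuple[float, float]
    mean: float | None = None
    sd: float | None = None
    params: dict = field(default_factory=dict)
    cdf: Callable[[float], float] | None = None

    def sample(self, size: int, seed: int | np.random.Generator) -> np.ndarray:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        draws = self.sampler(rng, size)
        lo, hi = self.support
        if np.any(draws < lo) or np.any(draws > hi):
            raise RuntimeError("sampler produced values outside the support")
        return draws

    def normalization_defect(self) -> float:
        """|1 - integral of pdf| by adaptive quadrature on the (truncated) support."""
        lo, hi = self.support
        if not math.isfinite(lo) or not math.isfinite(hi):
            # unbounded supports are checked over mean +/- 8 sd
            mu = self.mean if self.mean is not None else 0.0
            sd = self.sd if self.sd is not None else 1.0
            lo, hi = mu - 8 * sd, mu + 8 * sd
        total, _ = integrate.quad(self.pdf, lo, hi, limit=200)
        return abs(1.0 - total)


def gaussian_environment(mu: float, sigma: float) -> EnvironmentDistribution:
    """Gaussian environment ``X ~ N(mu, sigma)`` (sigma is the sd)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    dist = stats.norm(loc=mu, scale=sigma)
    return EnvironmentDistribution(
        family="gaussian",
        pdf=dist.pdf,
        sampler=lambda rng, n: rng.normal(mu, sigma, size=n),
        support=(-math.inf, math.inf),
        mean=float(mu),
        sd=float(sigma),
        params={"mu": float(mu), "sigma": float(sigma)},
        cdf=dist.cdf,
    )


def uniform_environment(lo: float, hi: float) -> EnvironmentDistribution:
    """Uniform environment on ``[lo, hi]``."""
    if not lo < hi:
        raise ValueError("need lo < hi")
    dist = stats.uniform(loc=lo, scale=hi - lo)
    return EnvironmentDistribution(
        family="uniform",
        pdf=dist.pdf,
        sampler=lambda rng, n: rng.uniform(lo, hi, size=n),
        support=(float(lo), float(hi)),
        mean=(lo + hi) / 2.0,
        sd=(hi - lo) / math.sqrt(12.0),
        params={"lo": float(lo), "hi": float(hi)},
        cdf=dist.cdf,
    )


def tabulated_environment(x: Sequence[float], density: Sequence[float]) -> EnvironmentDistribution:
    """Environment density given on a grid, renormalized and sampled by inverse CDF."""
    xs = np.asarray(x, dtype=float)
    ds = np.asarray(density, dtype=float)
    if xs.ndim != 1 or xs.shape != ds.shape or xs.size < 2:
        raise ValueError("need two equal-length 1-d arrays with >= 2 points")
    order = np.argsort(xs)
    xs, ds = xs[order], ds[order]
    if np.any(ds < 0):
        raise ValueError("density values must be nonnegative")
    total = np.trapezoid(ds, xs)
    if total <= 0:
        raise ValueError("density integrates to zero")
    ds = ds / total
    # piecewise-linear CDF on the grid
    cdf_grid = np.concatenate([[0.0], np.cumsum(np.diff(xs) * (ds[1:] + ds[:-1]) / 2.0)])
    cdf_grid /= cdf_grid[-1]
    mean = float(np.trapezoid(xs * ds, xs))
    var = float(np.trapezoid((xs - mean) ** 2 * ds, xs))

    def sampler(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.interp(rng.uniform(0.0, 1.0, size=n), cdf_grid, xs)

    return EnvironmentDistribution(
        family="tabulated",
        pdf=lambda q: np.interp(q, xs, ds, left=0.0, right=0.0),
        sampler=sampler,
        support=(float(xs[0]), float(xs[-1])),
        mean=mean,
        sd=math.sqrt(var),
        params={"x": xs.tolist(), "density": ds.tolist()},
        cdf=lambda q: float(np.interp(q, xs, cdf_grid, left=0.0, right=1.0)),
    )


def environment_from_csv(path: str | Path) -> EnvironmentDistribution:
    """Read a tabulated environment density from a two-column CSV (x, density)."""
    xs, ds = _read_two_column_csv(path)
    return tabulated_environment(xs, ds)


# ---------------------------------------------------------------------------
# Trait distributions
# ---------------------------------------------------------------------------

class TraitDistribution(ABC):
    """Distribution of expected trait values induced by an environment.

    Exposes the first moment ``m1`` (the reference point of the tail-product
    replication criterion) and one-sided tail masses.
    """

    @property
    @abstractmethod
    def m1(self) -> float:
        """First moment, in trait units."""

    @abstractmethod
    def tail(self, y: float, side: str = "upper") -> float:
        """P(Y > y) for ``side='upper'``, P(Y < y) for ``side='lower'``.

        Mass exactly at ``y`` belongs to neither side, so for any ``y``
        ``tail(y,'upper') + tail(y,'lower') + P(Y == y) == 1``.
        """

    @staticmethod
    def _check_side(side: str) -> None:
        if side not in ("upper", "lower"):
            raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")


@dataclass(frozen=True)
class GaussianTrait(TraitDistribution):
    """Closed-form Gaussian trait distribution."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def m1(self) -> float:
        return self.mu

    @property
    def sd(self) -> float:
        return self.sigma

    def tail(self, y: float, side: str = "upper") -> float:
        self._check_side(side)
        if side == "upper":
            return float(stats.norm.sf(y, loc=self.mu, scale=self.sigma))
        return float(stats.norm.cdf(y, loc=self.mu, scale=self.sigma))


@dataclass(frozen=True)
class PointMassTrait(TraitDistribution):
    """Degenerate trait distribution concentrated at one value."""

    value: float

    @property
    def m1(self) -> float:
        return self.value

    @property
    def sd(self) -> float:
        return 0.0

    def tail(self, y: float, side: str = "upper") -> float:
        self._check_side(side)
        if side == "upper":
            return 1.0 if self.value > y else 0.0
        return 1.0 if self.value < y else 0.0


@dataclass(frozen=True)
class EmpiricalTrait(TraitDistribution):
    """Trait distribution represented by Monte-Carlo draws."""

    values: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("need a 1-d sample of size >= 2")

    @property
    def sample_size(self) -> int:
        return int(self.values.size)

    @property
    def m1(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))

    def tail(self, y: float, side: str = "upper") -> float:
        self._check_side(side)
        if side == "upper":
            return float(np.mean(self.values > y))
        return float(np.mean(self.values < y))

    def require_precision(self, min_samples: int = 1000) -> None:
        if self.sample_size < min_samples:
            raise PrecisionError(
                f"empirical trait distribution has {self.sample_size} draws; "
                f"tail estimation needs >= {min_samples} (pass "
                f"allow_small_sample=True to override)"
            )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def evaluate_norm(norm: ReactionNorm, x):
    """Expected trait value ``E(y | x) = h(x)``; errors outside the domain."""
    return norm(x)


def expected_shift(norm: ReactionNorm, x1: float, x2: float) -> float:
    """Expected trait displacement ``h(x2) - h(x1)`` between two environments.

    This is the amount by which the original study's confidence interval is
    shifted when replication is judged under a known change of environment.
    """
    return float(norm(x2)) - float(norm(x1))


def _env_mass_outside(env: EnvironmentDistribution, domain: tuple[float, float]) -> float:
    lo, hi = domain
    if env.cdf is None:
        return 0.0 if (env.support[0] >= lo and env.support[1] <= hi) else math.nan
    below = float(env.cdf(lo)) if math.isfinite(lo) else 0.0
    above = 1.0 - float(env.cdf(hi)) if math.isfinite(hi) else 0.0
    return below + above


def compose_distribution(
    norm: ReactionNorm,
    env: EnvironmentDistribution,
    method: str = "monte_carlo",
    n_samples: int = 100_000,
    seed: int | None = None,
) -> TraitDistribution:
    """Push the environment distribution through the reaction norm.

    Computes the induced distribution of expected trait values ``h(X)``,
    ``X ~ g``.  Closed forms exist for a flat norm (point mass at the
    constant) and a linear norm with Gaussian environment
    (``N(a + b*mu, |b|*sigma)``); everything else is Monte Carlo with a
    mandatory explicit seed.

    Parameters
    ----------
    method : {"closed_form", "monte_carlo"}
        Requesting ``closed_form`` for an unsupported norm/environment pair
        raises :class:`~replinorm.errors.UnsupportedMethodError`; there is
        never a silent fallback.
    """
    mass_out = _env_mass_outside(env, norm.domain)
    if not (mass_out < 1e-9):
        raise DomainError(
            f"environment places probability mass {mass_out:.3g} outside the "
            f"domain {norm.domain} of norm {norm.genotype_label!r}"
        )

    if method == "closed_form":
        if norm.shape_tag == "flat":
            value = norm.params.get("value")
            if value is None:
                # flat norm built from an opaque callable: evaluate anywhere valid
                probe = env.mean if env.mean is not None else sum(norm.domain) / 2
                value = float(norm(probe))
            return PointMassTrait(float(value))
        if norm.shape_tag == "linear" and env.family == "gaussian":
            a = norm.params["intercept"]
            b = norm.params["slope"]
            return GaussianTrait(a + b * env.params["mu"], abs(b) * env.params["sigma"])
        raise UnsupportedMethodError(
            f"no closed form for shape_tag={norm.shape_tag!r} with "
            f"{env.family!r} environment; use method='monte_carlo'"
        )

    if method == "monte_carlo":
        if n_samples < 2:
            raise ValueError("monte_carlo needs n_samples >= 2")
        if seed is None:
            raise ValueError("monte_carlo composition requires an explicit seed")
        x = env.sample(n_samples, seed)
        return EmpiricalTrait(np.asarray(norm(x), dtype=float), seed=seed)

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Small-effect ensembles and their Gaussian limit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmallEffectEnsemble:
    """Many independent zero-mean environmental factors of small effect.

    After dominating factors are removed (standardized or modelled), the
    residual environmental influence on the trait is the sum of many
    independent small contributions; by the central limit theorem that sum
    is approximately Gaussian with variance equal to the sum of the factor
    variances.

    ``factors`` holds frozen scipy distributions, each with mean 0 and
    finite positive variance.
    """

    factors: tuple

    def __post_init__(self) -> None:
        for k, f in enumerate(self.factors):
            v = float(f.var())
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"factor {k} has invalid variance {v}")

    @property
    def count(self) -> int:
        return len(self.factors)

    @property
    def total_variance(self) -> float:
        return float(sum(f.var() for f in self.factors))

    @classmethod
    def iid_uniform(cls, count: int, half_width: float) -> "SmallEffectEnsemble":
        """``count`` iid Uniform(-half_width, half_width) factors."""
        f = stats.uniform(loc=-half_width, scale=2 * half_width)
        return cls(tuple([f] * count))

    @classmethod
    def iid_gaussian(cls, count: int, sd: float) -> "SmallEffectEnsemble":
        f = stats.norm(loc=0.0, scale=sd)
        return cls(tuple([f] * count))


def clt_aggregate(
    ensemble: SmallEffectEnsemble,
    n_samples: int,
    seed: int,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Sample the summed effect of an ensemble and report its Gaussian limit.

    Returns ``(samples, (0.0, sqrt(sum of factor variances)))``: each sample
    is the sum of one independent draw per factor; the second element gives
    the limiting Gaussian's mean and sd.

    An empty ensemble degenerates to a point mass at 0 (logged as a
    warning).
    """
    if n_samples < 2:
        raise ValueError("need n_samples >= 2")
    if ensemble.count == 0:
        logger.warning("clt_aggregate called with an empty ensemble; "
                       "returning a point mass at 0")
        return np.zeros(n_samples), (0.0, 0.0)
    rng = np.random.default_rng(seed)
    total = np.zeros(n_samples)
    for f in ensemble.factors:
        total += f.rvs(size=n_samples, random_state=rng)
    return total, (0.0, math.sqrt(ensemble.total_variance))
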