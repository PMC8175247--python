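"""Reaction norms, environment distributions, composition and the CLT limit."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import replinorm as rn
from replinorm.errors import DomainError, UnsupportedMethodError


class TestEvaluateNorm:
    def test_flat_norm_ignores_environment(self):
        norm = rn.flat_norm(3.0, "g2")
        assert rn.evaluate_norm(norm, 0.2) == 3.0
        assert rn.evaluate_norm(norm, 0.9) == 3.0

    def test_identity_norm(self):
        norm = rn.linear_norm(0.0, 1.0)
        assert rn.evaluate_norm(norm, 1.7) == pytest.approx(1.7)

    def test_two_genotypes_cross(self):
        # h1(x)=2x and h2(x)=4-2x intersect at x=1 with common value 2
        g1 = rn.linear_norm(0.0, 2.0, "g1")
        g2 = rn.linear_norm(4.0, -2.0, "g2")
        assert rn.evaluate_norm(g1, 1.0) == pytest.approx(2.0)
        assert rn.evaluate_norm(g2, 1.0) == pytest.approx(2.0)

    def test_outside_domain_errors_with_interval(self):
        norm = rn.linear_norm(0.0, 1.0, domain=(0.0, 2.0))
        with pytest.raises(DomainError, match=r"\[0.0, 2.0\]"):
            rn.evaluate_norm(norm, 2.5)

    def test_tabulated_norm_interpolates_but_never_extrapolates(self):
        norm = rn.tabulated_norm([0.0, 1.0, 2.0], [0.0, 2.0, 2.0])
        assert norm(0.5) == pytest.approx(1.0)
        with pytest.raises(DomainError):
            norm(-0.1)
        with pytest.raises(DomainError):
            norm(2.1)


class TestExpectedShift:
    @pytest.mark.parametrize("norm, x1, x2, expected", [
        (rn.flat_norm(7.0), -1.3, 2.4, 0.0),
        (rn.linear_norm(0.0, 2.0), 0.0, 1.0, 2.0),
        (rn.quadratic_norm(0.0, 0.0, 1.0), -1.0, 1.0, 0.0),
    ])
    def test_worked_values(self, norm, x1, x2, expected):
        assert rn.expected_shift(norm, x1, x2) == pytest.approx(expected)

    @given(
        a=st.floats(-5, 5), b=st.floats(-5, 5), c=st.floats(-2, 2),
        x1=st.floats(-3, 3), x2=st.floats(-3, 3),
    )
    def test_antisymmetry(self, a, b, c, x1, x2):
        norm = rn.quadratic_norm(a, b, c)
        assert rn.expected_shift(norm, x1, x2) == pytest.approx(
            -rn.expected_shift(norm, x2, x1), abs=1e-9)


class TestEnvironmentDistributions:
    @pytest.mark.parametrize("env", [
        rn.gaussian_environment(2.0, 3.0),
        rn.uniform_environment(-1.0, 4.0),
        rn.tabulated_environment(np.linspace(0, 1, 51), np.linspace(0, 2, 51)),
    ], ids=["gaussian", "uniform", "tabulated"])
    def test_pdf_normalizes_and_sampler_respects_support(self, env):
        assert env.normalization_defect() < 1e-6
        draws = env.sample(2000, seed=11)
        lo, hi = env.support
        assert np.all(draws >= lo) and np.all(draws <= hi)
        assert np.all(env.pdf(draws) >= 0)

    def test_tabulated_moments_match_triangular_density(self):
        # density proportional to x on [0,1]: mean 2/3, var 1/18
        env = rn.tabulated_environment(np.linspace(0, 1, 201),
                                       np.linspace(0, 1, 201))
        assert env.mean == pytest.approx(2 / 3, abs=1e-3)
        assert env.sd == pytest.approx(math.sqrt(1 / 18), abs=1e-3)


class TestComposeDistribution:
    def test_linear_gaussian_closed_form(self, std_env):
        dist = rn.compose_distribution(rn.linear_norm(1.0, 2.0), std_env,
                                       "closed_form")
        assert isinstance(dist, rn.GaussianTrait)
        assert (dist.mu, dist.sigma) == (1.0, 2.0)

    def test_closed_form_matches_monte_carlo(self, std_env):
        norm = rn.linear_norm(1.0, 2.0)
        closed = rn.compose_distribution(norm, std_env, "closed_form")
        mc = rn.compose_distribution(norm, std_env, "monte_carlo",
                                     n_samples=100_000, seed=42)
        se_mean = closed.sigma / math.sqrt(mc.sample_size)
        assert abs(mc.m1 - closed.mu) < 4 * se_mean
        # sd of the sample sd is approximately sigma/sqrt(2n)
        assert abs(mc.sd - closed.sigma) < 4 * closed.sigma / math.sqrt(2 * mc.sample_size)

    @pytest.mark.parametrize("env", [
        rn.gaussian_environment(0.0, 1.0),
        rn.uniform_environment(-2.0, 2.0),
    ], ids=["gaussian", "uniform"])
    def test_flat_norm_collapses_to_point_mass(self, env):
        dist = rn.compose_distribution(rn.flat_norm(5.0), env, "closed_form")
        assert isinstance(dist, rn.PointMassTrait)
        assert dist.m1 == 5.0 and dist.sd == 0.0

    def test_unsupported_closed_form_raises_not_falls_back(self, std_env):
        with pytest.raises(UnsupportedMethodError):
            rn.compose_distribution(rn.quadratic_norm(0, 0, 1), std_env,
                                    "closed_form")

    def test_monte_carlo_requires_explicit_seed(self, std_env):
        with pytest.raises(ValueError, match="seed"):
            rn.compose_distribution(rn.linear_norm(0, 1), std_env,
                                    "monte_carlo", n_samples=100)

    def test_quadratic_pushforward_first_moment(self, std_env):
        # E[X^2] = 1 for standard Gaussian; var(X^2) = 2
        dist = rn.compose_distribution(rn.quadratic_norm(0, 0, 1), std_env,
                                       "monte_carlo", n_samples=100_000, seed=3)
        se = math.sqrt(2.0 / dist.sample_size)
        assert abs(dist.m1 - 1.0) < 3 * se

    def test_env_mass_outside_domain_rejected(self):
        norm = rn.linear_norm(0.0, 1.0, domain=(-1.0, 1.0))
        with pytest.raises(DomainError):
            rn.compose_distribution(norm, rn.gaussian_environment(0.0, 1.0),
                                    "monte_carlo", n_samples=100, seed=1)


class TestTraitDistributionTails:
    @pytest.mark.parametrize("dist", [
        rn.GaussianTrait(0.5, 2.0),
        rn.EmpiricalTrait(np.random.default_rng(0).normal(size=5000)),
    ], ids=["gaussian", "empirical"])
    @pytest.mark.parametrize("y", [-1.0, 0.0, 1.5])
    def test_tails_partition_unit_mass(self, dist, y):
        point = 0.0
        if isinstance(dist, rn.EmpiricalTrait):
            point = float(np.mean(dist.values == y))
        assert dist.tail(y, "upper") + dist.tail(y, "lower") + point == pytest.approx(1.0)

    def test_upper_tail_monotone_non_increasing(self):
        dist = rn.GaussianTrait(0.0, 1.0)
        ys = np.linspace(-4, 4, 33)
        tails = [dist.tail(y, "upper") for y in ys]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_point_mass_tails(self):
        dist = rn.PointMassTrait(2.0)
        assert dist.tail(1.0, "upper") == 1.0
        assert dist.tail(2.0, "upper") == 0.0
        assert dist.tail(2.0, "lower") == 0.0


class TestCLTAggregate:
    def test_uniform_ensemble_limiting_sd(self):
        # var of Uniform(-0.1, 0.1) is 0.2^2/12; 100 factors sum to 1/3
        ens = rn.SmallEffectEnsemble.iid_uniform(100, 0.1)
        _, (mu, sd) = rn.clt_aggregate(ens, n_samples=10, seed=0)
        assert mu == 0.0
        assert sd == pytest.approx(math.sqrt(100 * 0.2 ** 2 / 12), abs=1e-12)

    def test_single_gaussian_factor_is_identity(self):
        ens = rn.SmallEffectEnsemble.iid_gaussian(1, 1.0)
        samples, (mu, sd) = rn.clt_aggregate(ens, n_samples=4000, seed=1)
        assert (mu, sd) == (0.0, 1.0)
        assert stats.kstest(samples, "norm").pvalue > 0.01

    def test_empty_ensemble_degenerates_with_warning(self, caplog):
        ens = rn.SmallEffectEnsemble(())
        with caplog.at_level(logging.WARNING, logger="replinorm.norms"):
            samples, (mu, sd) = rn.clt_aggregate(ens, n_samples=5, seed=0)
        assert np.all(samples == 0.0) and (mu, sd) == (0.0, 0.0)
        assert any("empty ensemble" in r.message for r in caplog.records)

    def test_aggregate_passes_normality_test(self):
        ens = rn.SmallEffectEnsemble.iid_uniform(200, 0.05)
        samples, (_, sd) = rn.clt_aggregate(ens, n_samples=10_000, seed=7)
        assert stats.kstest(samples, "norm", args=(0.0, sd)).pvalue > 0.01

    def test_gaussian_approximation_improves_with_factor_count(self):
        # fixed total variance 1, K growing: KS distance to N(0,1) shrinks
        distances = []
        for k in (2, 10, 100):
            half_width = math.sqrt(3.0 / k)  # var per factor = 1/k
            ens = rn.SmallEffectEnsemble.iid_uniform(k, half_width)
            ks = []
            for rep in range(5):
                samples, _ = rn.clt_aggregate(ens, n_samples=50_000,
                                              seed=100 * k + rep)
                ks.append(stats.kstest(samples, "norm").statistic)
            distances.append(np.mean(ks))
        assert distances[0] > distances[1] > distances[2]
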