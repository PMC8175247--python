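"""Replication-success criteria: naive, shifted-CI, tail-product, gradient."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

import replinorm as rn
from replinorm.errors import (
    CollinearityError,
    DegenerateSEError,
    MissingCovariateError,
    PrecisionError,
)
from conftest import make_study


class TestAssessNaive:
    @pytest.mark.parametrize("y2, expected", [
        (1.9, True),    # inside +/- 1.96
        (2.0, False),   # outside
        (1.96, False),  # exactly on the bound: strict inequality fails
    ])
    def test_inclusion_with_strict_bounds(self, y2, expected):
        a = rn.assess_naive(make_study(0.0, se=1.0), make_study(y2), z=1.96)
        assert a.success is expected
        assert a.interval == pytest.approx((-1.96, 1.96))

    def test_degenerate_se_rejected(self):
        bad = make_study(0.0, se=1.0)
        object.__setattr__(bad, "se", 0.0)
        with pytest.raises(DegenerateSEError):
            rn.assess_naive(bad, make_study(0.0))


class TestAssessShifted:
    def test_shift_moves_the_acceptance_interval(self):
        norm = rn.linear_norm(0.0, 2.0)
        orig = make_study(0.0, se=1.0, x=0.0)
        ok = rn.assess_shifted(orig, make_study(2.0, x=1.0), norm, z=1.96)
        assert ok.success and ok.shift == pytest.approx(2.0)
        assert ok.interval == pytest.approx((0.04, 3.96))
        bad = rn.assess_shifted(orig, make_study(0.0, x=1.0), norm, z=1.96)
        assert not bad.success

    def test_missing_covariate_directs_to_alternatives(self):
        norm = rn.flat_norm(0.0)
        with pytest.raises(MissingCovariateError, match="assess_naive"):
            rn.assess_shifted(make_study(0.0, x=None), make_study(1.0, x=1.0), norm)

    @given(
        y1=st.floats(-5, 5), y2=st.floats(-5, 5),
        se=st.floats(0.1, 3), z=st.floats(0.5, 3),
        x1=st.floats(-2, 2), x2=st.floats(-2, 2),
        m=st.floats(-10, 10),
    )
    def test_flat_norm_reduces_exactly_to_naive(self, y1, y2, se, z, x1, x2, m):
        norm = rn.flat_norm(m)
        orig = make_study(y1, se=se, x=x1)
        rep = make_study(y2, se=se, x=x2)
        assert rn.assess_shifted(orig, rep, norm, z=z).success == \
            rn.assess_naive(orig, rep, z=z).success

    @given(
        c=st.floats(-10, 10), y1=st.floats(-3, 3), y2=st.floats(-3, 3),
        slope=st.floats(-2, 2), x1=st.floats(-2, 2), x2=st.floats(-2, 2),
    )
    def test_shift_equivariance_under_trait_translation(self, c, y1, y2,
                                                        slope, x1, x2):
        base = rn.linear_norm(0.0, slope)
        lifted = rn.linear_norm(c, slope)
        a = rn.assess_shifted(make_study(y1, x=x1), make_study(y2, x=x2), base)
        b = rn.assess_shifted(make_study(y1 + c, x=x1), make_study(y2 + c, x=x2),
                              lifted)
        assert a.success == b.success


class TestAssessTailProduct:
    def test_symmetric_maximum_at_the_first_moment(self):
        a = rn.assess_tail_product(0.0, 0.0, rn.GaussianTrait(0.0, 1.0), L=0.2)
        assert a.product == pytest.approx(0.25, abs=1e-12)
        assert a.success

    def test_worked_gaussian_value(self):
        a = rn.assess_tail_product(1.0, -0.5, rn.GaussianTrait(0.0, 1.0))
        expected = stats.norm.sf(1.0) * stats.norm.cdf(-0.5)
        assert a.product == pytest.approx(expected, abs=1e-12)

    def test_far_tail_drives_failure(self):
        a = rn.assess_tail_product(5.0, 0.0, rn.GaussianTrait(0.0, 1.0), L=1e-4)
        assert not a.success
        assert a.product < 1e-4

    def test_quadrature_oracle_agreement(self):
        # tail masses from adaptive quadrature of the density itself
        dist = rn.GaussianTrait(0.3, 1.7)
        for y1, y2 in [(1.0, -0.5), (2.5, 2.5), (0.3, -4.0)]:
            a = rn.assess_tail_product(y1, y2, dist, L=1e-12)
            factors = []
            for y in (y1, y2):
                if y > dist.m1:
                    val, _ = integrate.quad(
                        lambda t: stats.norm.pdf(t, 0.3, 1.7), y, np.inf)
                elif y < dist.m1:
                    val, _ = integrate.quad(
                        lambda t: stats.norm.pdf(t, 0.3, 1.7), -np.inf, y)
                else:
                    val = 0.5
                factors.append(val)
            assert a.product == pytest.approx(factors[0] * factors[1], abs=1e-10)

    def test_product_bounded_by_quarter_on_grid(self):
        dist = rn.GaussianTrait(0.0, 1.0)
        grid = np.linspace(-3, 3, 13)
        products = np.array([[rn.assess_tail_product(a, b, dist, L=1e-15).product
                              for a in grid] for b in grid])
        assert products.max() <= 0.25 + 1e-12
        at_m1 = rn.assess_tail_product(0.0, 0.0, dist, L=1e-15).product
        assert at_m1 == pytest.approx(0.25, abs=1e-12)

    def test_product_shrinks_as_a_mean_leaves_m1(self):
        dist = rn.GaussianTrait(0.0, 1.0)
        prods = [rn.assess_tail_product(y, 0.5, dist, L=1e-15).product
                 for y in (0.0, 0.5, 1.0, 2.0, 3.0)]
        assert all(a >= b for a, b in zip(prods, prods[1:]))

    def test_empirical_distribution_precision_guard(self):
        small = rn.EmpiricalTrait(np.random.default_rng(0).normal(size=100))
        with pytest.raises(PrecisionError):
            rn.assess_tail_product(0.0, 0.0, small)
        a = rn.assess_tail_product(0.0, 0.0, small, allow_small_sample=True)
        assert 0.0 <= a.product <= 0.3

    def test_empirical_agrees_with_closed_form(self, std_env):
        dist = rn.compose_distribution(rn.linear_norm(0.0, 1.0), std_env,
                                       "monte_carlo", n_samples=100_000, seed=8)
        a = rn.assess_tail_product(1.0, -0.5, dist)
        expected = stats.norm.sf(1.0) * stats.norm.cdf(-0.5)
        assert a.product == pytest.approx(expected, abs=0.01)


class TestReproducibilityRate:
    def test_identical_pairs_always_replicate(self):
        pairs = [(make_study(1.0), make_study(1.0)) for _ in range(10)]
        rate, (lo, hi) = rn.reproducibility_rate(pairs, "naive")
        assert rate == 1.0
        assert lo < 1.0  # Wilson interval is informative, not degenerate
        assert hi == pytest.approx(1.0)

    def test_empty_input_is_a_structural_error(self):
        with pytest.raises(rn.StructuralError):
            rn.reproducibility_rate([], "naive")

    def test_shifted_criterion_beats_naive_under_a_dominating_factor(self):
        # pairs of standardized-within, displaced-between studies: each lab
        # sits at its own environment value; the naive criterion is blind to
        # the displacement, the shifted criterion conditions it away.
        rng = np.random.default_rng(17)
        norm = rn.linear_norm(0.0, 1.0)
        env = rn.gaussian_environment(0.0, 1.0)
        pairs = []
        for _ in range(500):
            x1, x2 = env.sample(2, rng)
            se = 0.3
            # the treatment effect itself depends on the environment
            y1 = (1.0 + x1) + rng.normal(0, se)
            y2 = (1.0 + x2) + rng.normal(0, se)
            pairs.append((make_study(y1, se=se, x=float(x1)),
                          make_study(y2, se=se, x=float(x2))))
        naive_rate, _ = rn.reproducibility_rate(pairs, "naive")
        shifted_rate, _ = rn.reproducibility_rate(pairs, "shifted_ci", norm=norm)
        assert naive_rate < shifted_rate
        # the shifted interval uses only the original SE, so its coverage
        # target is P(|N(0, sqrt(2)*se)| < z*se) = 2*Phi(z/sqrt(2)) - 1
        target = 2 * stats.norm.cdf(1.96 / math.sqrt(2)) - 1
        assert shifted_rate == pytest.approx(target, abs=0.05)
        assert naive_rate < 0.6


class TestConditionalEffectRegression:
    def test_noise_free_linear_collection_is_fit_exactly(self):
        studies = [make_study(1.0 + 2.0 * x, se=0.5, x=x, lab=f"s{i}")
                   for i, x in enumerate(np.linspace(0, 4, 9))]
        fit = rn.conditional_effect_regression(studies)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.success.all()

    def test_null_gradient_rarely_declared_significant(self):
        # delta1 = 0: the fitted slope should be within 1.96 slope-SEs of 0
        # in about 95% of replicates
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            studies = rn.make_gradient_fixture(delta0=1.0, delta1=0.0,
                                               se_per_study=0.3, seed=rep)
            fit = rn.conditional_effect_regression(studies)
            hits += abs(fit.slope) < 1.96 * fit.slope_se
        assert hits / n_rep >= 0.90

    def test_identical_covariates_raise_collinearity(self):
        studies = [make_study(float(i), x=1.0, lab=f"s{i}") for i in range(5)]
        with pytest.raises(CollinearityError):
            rn.conditional_effect_regression(studies)

    def test_missing_covariate_rejected(self):
        studies = [make_study(0.0, x=None, lab="a"),
                   make_study(0.0, x=1.0, lab="b"),
                   make_study(0.0, x=2.0, lab="c")]
        with pytest.raises(MissingCovariateError):
            rn.conditional_effect_regression(studies)
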