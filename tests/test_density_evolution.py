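import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.stats import binom

from boolfg import (
    DegreeDistribution,
    critical_degree3_mass,
    de_evolve,
    de_step,
    degree_distribution,
    degree_error,
    first_order_coefficients,
    li_yeast_network,
    pairwise_error_update,
    resilience_check,
    simulate_de_round,
)

from conftest import LI_RHO


def single_degree(j):
    return DegreeDistribution({j: 1.0})


def pattern_oracle(y, j):
    """Exhaustive enumeration over all 2^(j-1) error patterns."""
    m = j - 1
    total = 0.0
    for pattern in itertools.product((0, 1), repeat=m):
        errors = sum(pattern)
        if errors >= math.ceil(m / 2):
            total += y**errors * (1 - y) ** (m - errors)
    return total


class TestPairwiseErrorUpdate:
    @pytest.mark.parametrize("eps,expected", [(0.0, 0.0), (1.0, 0.5), (0.25, 0.21875)])
    def test_closed_form_values(self, eps, expected):
        assert pairwise_error_update(eps) == pytest.approx(expected, abs=1e-15)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            pairwise_error_update(-0.1)


class TestDegreeError:
    @pytest.mark.parametrize("j", range(1, 13))
    def test_matches_pattern_enumeration_oracle(self, j):
        for y in (0.0, 0.1, 0.25, 0.5, 0.9, 1.0):
            assert degree_error(y, j) == pytest.approx(pattern_oracle(y, j), abs=1e-12)

    def test_degree_two_is_identity(self):
        for y in (0.0, 0.3, 0.7):
            assert degree_error(y, 2) == pytest.approx(y, abs=1e-15)

    def test_degree_three_half(self):
        assert degree_error(0.5, 3) == pytest.approx(0.75)

    def test_degree_one_is_constant_error(self):
        assert degree_error(0.0, 1) == 1.0
        assert degree_error(0.7, 1) == 1.0

    def test_agrees_with_binomial_survival(self):
        # independent cross-check against the scipy binomial tail
        for j in (4, 7, 10):
            m = j - 1
            lower = math.ceil(m / 2)
            for y in (0.2, 0.6):
                assert degree_error(y, j) == pytest.approx(
                    binom.sf(lower - 1, m, y), abs=1e-12
                )

    @settings(derandomize=True, max_examples=60)
    @given(
        st.integers(1, 9),
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
    )
    def test_monotone_in_y(self, j, y1, y2):
        lo, hi = sorted((y1, y2))
        assert degree_error(lo, j) <= degree_error(hi, j) + 1e-12

    def test_invalid_degree(self):
        with pytest.raises(ValueError):
            degree_error(0.5, 0)


class TestDEStep:
    def test_zero_is_fixed_point_iff_no_degree_one_mass(self):
        assert de_step(0.0, DegreeDistribution({2: 0.5, 4: 0.5})) == 0.0
        li = DegreeDistribution(LI_RHO)
        assert de_step(0.0, li) == pytest.approx(0.025, abs=1e-15)

    def test_single_degree_two_reduces_to_pairwise(self):
        for eps in (0.1, 0.25, 0.8):
            assert de_step(eps, single_degree(2)) == pytest.approx(
                pairwise_error_update(eps), abs=1e-15
            )

    def test_maps_unit_interval_into_itself(self):
        li = DegreeDistribution(LI_RHO)
        for eps in np.linspace(0, 1, 21):
            assert 0.0 <= de_step(float(eps), li) <= 1.0


class TestDEEvolve:
    def test_degree_three_limit_matches_fixed_point_equation(self):
        # analytic oracle: the stable fixed point of e = 2y(1-y) + y^2
        def gap(e):
            y = e * (1 - e / 2)
            return 2 * y * (1 - y) + y**2 - e

        fixed_point = brentq(gap, 1e-6, 1.0)
        result = de_evolve(0.25, single_degree(3))
        assert result.converged
        assert result.limit == pytest.approx(fixed_point, abs=1e-9)

    def test_high_degree_errors_vanish(self):
        result = de_evolve(0.25, single_degree(4))
        assert result.converged and result.limit == pytest.approx(0.0, abs=1e-12)

    def test_zero_start_stays_zero_without_degree_one(self):
        result = de_evolve(0.0, single_degree(5), max_iter=10)
        assert set(result.epsilons) == {0.0}

    def test_limit_bounded_below_by_degree_one_mass(self):
        li = DegreeDistribution(LI_RHO)
        result = de_evolve(0.25, li)
        assert result.limit >= li.rho(1)
        assert all(e >= li.rho(1) for e in result.epsilons[1:])

    def test_every_iterate_is_a_probability(self):
        for rho in (single_degree(1), single_degree(3), DegreeDistribution(LI_RHO)):
            result = de_evolve(0.9, rho, max_iter=50)
            assert all(0.0 <= e <= 1.0 for e in result.epsilons)


class TestFirstOrderAndResilience:
    def test_li_coefficients(self):
        rho = degree_distribution(li_yeast_network())
        assert first_order_coefficients(rho) == pytest.approx((0.025, 0.65))

    @pytest.mark.parametrize(
        "coeffs,expected",
        [({4: 1.0}, (0.0, 0.0)), ({1: 1.0}, (1.0, 0.0))],
    )
    def test_degenerate_coefficients(self, coeffs, expected):
        assert first_order_coefficients(DegreeDistribution(coeffs)) == expected

    def test_li_network_is_not_first_order_resilient(self):
        verdict = resilience_check(degree_distribution(li_yeast_network()))
        assert not verdict.resilient
        assert not verdict.rho1_zero  # the orphan Cln3 node pins the error floor
        assert verdict.error_floor == pytest.approx(0.025 / 0.35)

    def test_pure_high_degree_is_resilient(self):
        assert resilience_check(single_degree(4)).resilient

    def test_heavy_degree_three_mass_fails(self):
        rho = DegreeDistribution({3: 0.6, 5: 0.4})
        verdict = resilience_check(rho)
        assert not verdict.resilient and not verdict.rho3_ok
        # cross-check: the recursion indeed does not die out
        result = de_evolve(0.25, rho)
        assert result.limit > 0.01

    def test_critical_degree3_mass_is_half(self):
        assert critical_degree3_mass() == pytest.approx(0.5, abs=1e-9)
        # independent of which high degree absorbs the remaining mass
        assert critical_degree3_mass(high_degree=8) == pytest.approx(0.5, abs=1e-9)


class TestMonteCarloConsistency:
    def test_one_round_simulation_matches_recursion(self):
        rho = DegreeDistribution(LI_RHO)
        eps = 0.25
        n = 60_000
        predicted = de_step(eps, rho)
        observed = simulate_de_round(rho, eps, n, np.random.default_rng(2024))
        sigma = math.sqrt(predicted * (1 - predicted) / n)
        assert abs(observed - predicted) < 3 * sigma
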