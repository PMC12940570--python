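"""Steady state, fluxes, force, and entropy-production decomposition."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cycledissip import (
    CycleScheme,
    SchemeError,
    closed_form_flux,
    edge_entropy_production,
    king_altman_denominator,
    one_way_fluxes,
    solve_steady_state,
    thermodynamic_force,
    force_from_mass_action,
)

from conftest import dense_steady_state, equilibrium_scheme, random_scheme


class TestEquilibrium:
    def test_symmetric_two_state_is_dead(self):
        st_ = solve_steady_state(CycleScheme((1.0, 1.0), (1.0, 1.0)))
        assert st_.probabilities == pytest.approx([0.5, 0.5], abs=0)
        assert st_.net_flux == 0.0
        assert st_.force_rt == 0.0
        assert st_.dissipation_rt == 0.0
        assert np.all(st_.edge_sigma_rt == 0.0)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_detailed_balance_zeroes_everything_exactly(self, rng, n):
        for _ in range(25):
            st_ = solve_steady_state(equilibrium_scheme(rng, n))
            assert st_.net_flux == 0.0
            assert st_.force_rt == 0.0
            assert st_.dissipation_rt == 0.0
            assert np.all(st_.edge_sigma_rt == 0.0)
            assert st_.forward_flux == st_.backward_flux


class TestAgainstExactDenseSolve:
    """The King--Altman solver vs exact-rational Gaussian elimination."""

    def test_three_state_reference(self, toy3):
        st_ = solve_steady_state(toy3)
        p_exact, j_exact = dense_steady_state(toy3)
        for p_num, p_ref in zip(st_.probabilities, p_exact):
            assert p_num == pytest.approx(float(p_ref), rel=1e-12)
        assert st_.net_flux == pytest.approx(float(j_exact), rel=1e-12)
        assert closed_form_flux(toy3) == pytest.approx(float(j_exact), rel=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_random_schemes(self, rng, n):
        for _ in range(50):
            s = random_scheme(rng, n)
            st_ = solve_steady_state(s)
            p_exact, j_exact = dense_steady_state(s)
            for p_num, p_ref in zip(st_.probabilities, p_exact):
                assert p_num == pytest.approx(float(p_ref), rel=1e-9)
            assert st_.net_flux == pytest.approx(float(j_exact), rel=1e-9)
            assert closed_form_flux(s) == pytest.approx(float(j_exact), rel=1e-9)


class TestOneWayFluxes:
    def test_equilibrium_fluxes_balance(self, rng):
        s = equilibrium_scheme(rng, 3)
        j_plus, j_minus = one_way_fluxes(s)
        assert j_plus == j_minus

    def test_flux_ratio_equals_exp_force(self, toy3):
        st_ = solve_steady_state(toy3)
        assert st_.forward_flux / st_.backward_flux == pytest.approx(math.exp(st_.force_rt), rel=1e-9)
        assert st_.forward_flux - st_.backward_flux == pytest.approx(st_.net_flux, rel=1e-12)

    def test_product_rebinding_off_kills_backward_flux(self, toy3):
        # k6 -> 0: J- -> 0 (proportionally to k6) and J -> J+
        ratios = []
        for k6 in (1e-6, 1e-9, 1e-12):
            st_ = solve_steady_state(toy3.replace_rate(2, reverse=k6))
            ratios.append(st_.backward_flux / st_.forward_flux)
        assert ratios[1] == pytest.approx(ratios[0] * 1e-3, rel=1e-3)
        assert ratios[2] < 1e-12
        assert st_.net_flux == pytest.approx(st_.forward_flux, rel=1e-9)

    def test_denominator_matches_flux_decomposition(self, toy3):
        sigma = king_altman_denominator(toy3)
        j_plus, j_minus = one_way_fluxes(toy3)
        assert j_plus == pytest.approx(math.prod(toy3.forward_rates) / sigma, rel=1e-12)
        assert j_minus == pytest.approx(math.prod(toy3.reverse_rates) / sigma, rel=1e-12)


class TestEdgeEntropyProduction:
    def test_all_edges_zero_at_equilibrium(self, rng):
        s = equilibrium_scheme(rng, 4)
        st_ = solve_steady_state(s)
        for e in range(4):
            assert edge_entropy_production(s, st_, e) == 0.0

    def test_decomposition_sums_to_total(self, toy3):
        st_ = solve_steady_state(toy3)
        total = sum(edge_entropy_production(toy3, st_, e) for e in range(3))
        assert total == pytest.approx(st_.net_flux * st_.force_rt, rel=1e-12)

    def test_alternative_index_convention_agrees(self, toy3):
        # sigma via transition-matrix elements W[i][j] = rate j -> i:
        # (W_ij p_j - W_ji p_i) log(W_ij p_j / (W_ji p_i)) is the same
        # quantity with source state written second.
        st_ = solve_steady_state(toy3)
        n = toy3.n_states
        w = [[0.0] * n for _ in range(n)]
        for e in range(n):
            j = (e + 1) % n
            w[j][e] = toy3.forward_rates[e]
            w[e][j] = toy3.reverse_rates[e]
        p = st_.probabilities
        for e in range(n):
            j = (e + 1) % n
            a, b = w[j][e] * p[e], w[e][j] * p[j]
            alt = (a - b) * math.log(a / b)
            assert alt == pytest.approx(edge_entropy_production(toy3, st_, e), rel=1e-12)

    def test_invalid_edge_raises(self, toy3):
        st_ = solve_steady_state(toy3)
        with pytest.raises(SchemeError):
            edge_entropy_production(toy3, st_, 3)


class TestForce:
    def test_unit_force_construction(self):
        # 2-state with k1 k3 / (k2 k4) = e  =>  X/RT = 1
        s = CycleScheme((math.e, 1.0), (1.0, 1.0))
        assert thermodynamic_force(s) == pytest.approx(1.0, rel=1e-12)

    def test_telescoping_sum_over_edges(self, rng):
        # X/RT equals the sum over edges of ln(k_ij p_i / (k_ji p_j))
        for _ in range(20):
            s = random_scheme(rng, 4)
            st_ = solve_steady_state(s)
            p = st_.probabilities
            total = math.fsum(
                math.log(s.forward_rates[e] * p[e] / (s.reverse_rates[e] * p[(e + 1) % 4]))
                for e in range(4)
            )
            assert total == pytest.approx(st_.force_rt, rel=1e-9)

    def test_mass_action_convention(self):
        # Gamma < K_eq must give positive force (forward drive)
        assert force_from_mass_action(1e-3, 1.0) == pytest.approx(math.log(1000.0))
        assert force_from_mass_action(10.0, 1.0) < 0
        with pytest.raises(ValueError):
            force_from_mass_action(-1.0, 1.0)

    def test_force_in_energy_units(self):
        s = CycleScheme((math.e, 1.0), (1.0, 1.0))
        assert thermodynamic_force(s, per_rt=False) == pytest.approx(8.314 * 298.15, rel=1e-9)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    n=st.integers(2, 4),
    seed=st.integers(0, 2**31 - 1),
    x=st.floats(0.1, 40.0),
)
def test_conservation_and_second_law_properties(n, seed, x):
    """Sum of edge sigmas equals J*X/RT; dissipation nonnegative; sign(J) = sign(X)."""
    s = random_scheme(np.random.default_rng(seed), n, force_rt=x)
    st_ = solve_steady_state(s)
    assert st_.dissipation_rt >= 0.0
    assert np.all(st_.edge_sigma_rt >= 0.0)
    assert math.fsum(st_.edge_sigma_rt) == pytest.approx(st_.dissipation_rt, rel=1e-9)
    assert (st_.net_flux > 0) == (st_.force_rt > 0)
    assert st_.forward_flux >= st_.backward_flux


def test_flux_monotone_in_each_forward_rate(rng):
    """At fixed other constants, J never decreases in any forward rate."""
    for _ in range(10):
        s = random_scheme(rng, 3)
        for edge in range(3):
            k0 = s.forward_rates[edge]
            fluxes = [
                solve_steady_state(s.replace_rate(edge, forward=k0 * f)).net_flux
                for f in np.logspace(-2, 2, 9)
            ]
            diffs = np.diff(fluxes)
            assert np.all(diffs >= -1e-12 * np.abs(fluxes[:-1]))
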