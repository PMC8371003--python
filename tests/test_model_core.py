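"""Unit and property tests for the model types and right-hand sides."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from reeffishery import (
    ConfigurationError,
    Parameters,
    ZoneState,
    attraction,
    full_rhs,
    nu1_star,
    reduced_rhs,
    zone_capacities,
)
from reeffishery.equilibrium import harvest_weight, interior_equilibrium, k_eff

def mk(**overrides):
    base = dict(V=0.0, gamma=0.0, beta0=1.0, delta_k=5.0)
    base.update(overrides)
    return Parameters(**base)


# randomized-but-valid parameter draws for property tests
valid_params = st.builds(
    Parameters,
    V=st.floats(0.0, 600.0),
    gamma=st.floats(0.0, 1.0),
    beta0=st.floats(0.0, 2.0),
    delta_k=st.floats(0.0, 5.0),
    r=st.floats(0.1, 2.0),
    K=st.floats(10.0, 500.0),
    a=st.floats(0.5, 5.0),
    c=st.floats(0.2, 5.0),
    p=st.floats(0.2, 5.0),
    alpha=st.floats(0.05, 0.9),
    sigma=st.floats(0.01, 0.5),
)


class TestParameters:
    def test_rejects_out_of_range_values(self):
        with pytest.raises(ConfigurationError, match="alpha"):
            Parameters(V=0, gamma=0, beta0=1, delta_k=5, alpha=1.5)
        with pytest.raises(ConfigurationError, match="gamma"):
            Parameters(V=0, gamma=-0.1, beta0=1, delta_k=5)
        with pytest.raises(ConfigurationError, match="V"):
            Parameters(V=-1, gamma=0, beta0=1, delta_k=5)
        with pytest.raises(ConfigurationError, match="r"):
            Parameters(V=0, gamma=0, beta0=1, delta_k=5, r=0.0)
        with pytest.raises(ConfigurationError, match="attraction_form"):
            Parameters(V=0, gamma=0, beta0=1, delta_k=5, attraction_form="nope")

    @given(gamma=st.floats(0.001, 0.999))
    def test_fast_effort_rates_split_as_gamma(self, gamma):
        p = Parameters(V=0, gamma=gamma, beta0=1, delta_k=5)
        assert p.m1 / (p.m1 + p.m2) == pytest.approx(gamma, rel=1e-12)


class TestAttraction:
    @pytest.mark.parametrize("form", ["multiplicative_saturating", "absolute_saturating", "linear"])
    def test_vanishes_without_reef(self, form, make_params):
        assert attraction(0.0, make_params(attraction_form=form)) == 0.0

    def test_default_form_worked_value(self, make_params):
        # beta0 * a/((1-alpha)K) * (1 - e^{-sigma V}) at V=120
        p = make_params(V=120.0)
        assert attraction(120.0, p) == pytest.approx(0.025 * (1 - math.exp(-12.0)), rel=1e-12)
        assert attraction(120.0, p) == pytest.approx(0.0250, abs=5e-5)

    def test_saturates_at_baseline_rate_multiple(self, make_params):
        p = make_params()
        big = attraction(200.0, p)
        assert big < 0.025
        assert big == pytest.approx(0.025, rel=1e-8)

    def test_negative_volume_rejected(self, make_params):
        with pytest.raises((ConfigurationError, ValueError)):
            attraction(-1.0, make_params())

    @given(v1=st.floats(0.0, 1e3), v2=st.floats(0.0, 1e3))
    @pytest.mark.parametrize("form", ["multiplicative_saturating", "absolute_saturating", "linear"])
    def test_nonnegative_and_nondecreasing(self, form, v1, v2):
        p = mk(attraction_form=form)
        lo, hi = sorted((v1, v2))
        b_lo, b_hi = attraction(lo, p), attraction(hi, p)
        assert b_lo >= 0.0
        assert b_hi >= b_lo - 1e-15


class TestZoneCapacities:
    @pytest.mark.parametrize(
        "V, delta_k, expected",
        [(0.0, 5.0, (20.0, 80.0)), (120.0, 5.0, (620.0, 80.0)), (120.0, 0.1, (32.0, 80.0))],
    )
    def test_worked_values(self, make_params, V, delta_k, expected):
        K1, K2 = zone_capacities(make_params(V=V, delta_k=delta_k))
        assert (K1, K2) == pytest.approx(expected)


class TestNu1Star:
    def test_ifd_without_reef(self, make_params):
        assert nu1_star(make_params()) == pytest.approx(0.2, rel=1e-12)

    def test_ifd_limit_with_production_only(self, make_params):
        p = make_params(V=120.0, beta0=0.0)
        assert nu1_star(p) == pytest.approx(620.0 / 700.0, rel=1e-12)

    def test_attraction_shifts_distribution(self, make_params):
        assert nu1_star(make_params(V=120.0)) == pytest.approx(0.9394, abs=5e-5)

    @given(valid_params)
    @settings(max_examples=200, deadline=None)
    def test_ifd_limit_for_any_parameters_without_attraction(self, params):
        p = params.evolve(beta0=0.0)
        K1, K2 = zone_capacities(p)
        assert nu1_star(p) == pytest.approx(K1 / (K1 + K2), rel=1e-12)

    @pytest.mark.parametrize("V,beta0", [(0.0, 1.0), (120.0, 0.0), (120.0, 1.0), (500.0, 0.5)])
    def test_matches_fast_subsystem_integration(self, make_params, V, beta0):
        """nu1* is the long-time biomass share of the pure-movement subsystem."""
        p = make_params(V=V, beta0=beta0, epsilon=0.0)

        def movement(_t, y):
            return full_rhs(ZoneState(y[0], y[1], 0.0, 0.0), p)[:2]

        sol = solve_ivp(movement, (0.0, 5000.0), [30.0, 70.0], rtol=1e-11, atol=1e-12)
        n1, n2 = sol.y[:, -1]
        assert n1 / (n1 + n2) == pytest.approx(nu1_star(p), rel=1e-6)


class TestFullRhs:
    def test_extinction_is_equilibrium(self, make_params):
        assert full_rhs(ZoneState(0, 0, 0, 0), make_params(gamma=0.3)) == (0, 0, 0, 0)

    def test_fast_balance_state_has_only_slow_drift(self, make_params):
        """At n1/n2 = B/A and E1/E2 = m1/m2 the movement terms cancel exactly."""
        p = make_params(V=120.0, gamma=0.3)
        nu = nu1_star(p)
        n, E = 40.0, 0.6
        state = ZoneState(nu * n, (1 - nu) * n, p.gamma * E, (1 - p.gamma) * E)
        fast_only = full_rhs(state, p.evolve(epsilon=0.0))
        assert np.allclose(fast_only, 0.0, atol=1e-12)

    def test_hand_computed_slow_terms(self, make_params):
        p = make_params(gamma=0.5)  # V=0, Table-1 defaults, epsilon=0.1
        dn1, dn2, dE1, dE2 = full_rhs(ZoneState(10.0, 10.0, 0.0, 0.0), p)
        assert dn1 == pytest.approx(-0.5, abs=1e-12)
        assert dn2 == pytest.approx(1.1875, abs=1e-12)
        assert dE1 == 0.0 and dE2 == 0.0

    def test_rejects_negative_state(self, make_params):
        with pytest.raises(ValueError):
            full_rhs(ZoneState(-1.0, 0, 0, 0), make_params())

    @given(valid_params, st.integers(0, 3), st.floats(0.1, 50.0))
    @settings(max_examples=150, deadline=None)
    def test_zero_component_never_driven_negative(self, params, idx, fill):
        state = [fill] * 4
        state[idx] = 0.0
        d = full_rhs(ZoneState(*state), params)
        assert d[idx] >= 0.0


class TestReducedRhs:
    def test_interior_equilibrium_is_fixed_point(self, make_params):
        p = make_params(V=120.0, gamma=0.2)
        eq = interior_equilibrium(p)
        dn, dE = reduced_rhs((eq.n_star, eq.E_star), p)
        assert abs(dn) < 1e-10 and abs(dE) < 1e-10

    def test_unfished_stock_rests_at_aggregate_capacity(self, make_params):
        p = make_params(V=120.0)
        dn, dE = reduced_rhs((k_eff(p), 0.0), p)
        assert dn == pytest.approx(0.0, abs=1e-10)
        assert dE == 0.0

    def test_effort_decays_at_cost_rate_without_fish(self, make_params):
        p = make_params(gamma=0.5, c=1.7)
        dn, dE = reduced_rhs((0.0, 2.0), p)
        assert dn == 0.0
        assert dE == pytest.approx(-1.7 * 2.0, rel=1e-12)

    @given(valid_params, st.floats(0.1, 200.0), st.floats(0.0, 5.0))
    @settings(max_examples=150, deadline=None)
    def test_matches_two_patch_gordon_schaefer_without_reef(self, params, n, E):
        """With no reef the aggregation is an exact two-patch open-access model."""
        p = params.evolve(V=0.0, beta0=0.0)
        K1, K2 = zone_capacities(p)
        nu = K1 / (K1 + K2)
        q, g = p.q, p.gamma
        # hand-coded aggregate of a two-patch Gordon-Schaefer system on the IFD
        dn_ref = (
            p.r * n * (1 - (nu**2) * n / K1 - ((1 - nu) ** 2) * n / K2)
            - q * g * nu * n * E
            - q * (1 - g) * (1 - nu) * n * E
        )
        dE_ref = (p.p * q * (g * nu + (1 - g) * (1 - nu)) * n - p.c) * E
        dn, dE = reduced_rhs((n, E), p)
        assert dn == pytest.approx(dn_ref, rel=1e-12, abs=1e-12)
        assert dE == pytest.approx(dE_ref, rel=1e-12, abs=1e-12)

    @given(valid_params, st.floats(0.1, 100.0), st.floats(0.01, 5.0))
    @settings(max_examples=150, deadline=None)
    def test_fast_manifold_catch_terms_agree_with_full_model(self, params, n, E):
        """Zone harvests summed on the fast manifold equal the aggregate harvest term."""
        nu = nu1_star(params)
        n1, E1 = nu * n, params.gamma * E
        n2, E2 = (1 - nu) * n, (1 - params.gamma) * E
        zone_catch = params.q1 * n1 * E1 + params.q2 * n2 * E2
        aggregate_catch = params.q * harvest_weight(params) * n * E
        assert zone_catch == pytest.approx(aggregate_catch, rel=1e-10, abs=1e-10)
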