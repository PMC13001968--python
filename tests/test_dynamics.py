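"""Tests of the coupled-trait ODE system and its integrator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entrodyn.dynamics import (
    SET3_PARAMS,
    CoupledTraitParams,
    InitialCondition,
    metabolic_cost,
    rhs,
    selection_pressure,
    simulate,
)
from entrodyn.errors import InvalidInputError, SimulationError


def rk4_oracle(params, init, t_end, h=1e-3):
    """Independent fixed-step classical Runge-Kutta integrator."""
    p = params.effective()

    def f(t, y):
        N, P, E = y
        e = E
        if p.forcing_enabled:
            e = E + p.forcing_amplitude * math.sin(p.forcing_omega * (t - init.t0))
        return np.array([
            p.mu * N - (p.alpha * N + p.beta**2 * P) * N,
            p.mu * P - p.beta * P * (p.c1 * P + p.c2 * N + p.c3 * e) / p.G,
            p.gamma * E * N / (N + p.K),
        ])

    n_steps = int(round((t_end - init.t0) / h))
    y = init.state.copy()
    t = init.t0
    for _ in range(n_steps):
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h / 2 * k1)
        k3 = f(t + h / 2, y + h / 2 * k2)
        k4 = f(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return y


class TestTerms:
    def test_selection_pressure_vanishing_coefficients(self):
        p = CoupledTraitParams()
        assert selection_pressure(3.0, 7.0, p) == 0.0

    def test_selection_pressure_beta_sign_symmetry(self):
        p = CoupledTraitParams(alpha=1.0, beta=-0.5)
        assert selection_pressure(0.0, 1.0, p) == pytest.approx(0.25)
        p2 = CoupledTraitParams(alpha=1.0, beta=0.5)
        assert selection_pressure(0.0, 1.0, p2) == pytest.approx(0.25)

    def test_selection_pressure_illustrative_regime(self):
        # alpha*N + beta^2*P at N=P=1: 0.098 + 0.17117^2
        assert selection_pressure(1.0, 1.0, SET3_PARAMS) == pytest.approx(
            0.098 + 0.17117**2, abs=1e-12
        )

    def test_metabolic_cost_zero_weights(self):
        p = CoupledTraitParams()
        assert metabolic_cost(1.0, 0.5, 0.3, p) == 0.0

    def test_metabolic_cost_hand_evaluated(self):
        p = CoupledTraitParams(c1=2.0, c2=0.21)
        assert metabolic_cost(1.0, 0.5, 0.0, p) == pytest.approx(1.21, abs=1e-12)

    def test_forcing_phase_zero_matches_unforced(self):
        base = CoupledTraitParams(c1=1.0, c3=1.0)
        forced = CoupledTraitParams(c1=1.0, c3=1.0, forcing_enabled=True,
                                    forcing_amplitude=1.0, forcing_omega=2.0)
        assert metabolic_cost(0.4, 0.5, 0.2, forced, t=0.0, t0=0.0) == (
            metabolic_cost(0.4, 0.5, 0.2, base)
        )

    def test_forcing_modulates_cost_away_from_phase_zero(self):
        forced = CoupledTraitParams(c3=1.0, forcing_enabled=True,
                                    forcing_amplitude=0.5, forcing_omega=1.0)
        expected = 0.2 + 0.5 * math.sin(1.5)
        assert metabolic_cost(0.0, 0.0, 0.2, forced, t=1.5) == pytest.approx(expected)


class TestRHS:
    def test_origin_is_fixed_point(self):
        p = CoupledTraitParams(mu=0.3, alpha=1.0, beta=0.5, gamma=0.2,
                               c1=1.0, c2=1.0, c3=1.0)
        np.testing.assert_array_equal(rhs(0.0, [0, 0, 0], p), [0, 0, 0])

    def test_linear_growth_limit(self):
        p = CoupledTraitParams(mu=0.1)
        np.testing.assert_allclose(rhs(0.0, [2, 3, 1], p), [0.2, 0.3, 0.0])

    def test_illustrative_regime_term_by_term(self):
        # dN = mu*N - (alpha*N + beta^2*P)*N
        # dP = mu*P - beta*P*(c1*P + c2*N + c3*E)/G
        # dE = gamma*E*N/(N+K)
        d = rhs(0.0, [0.9, 0.93, 0.01], SET3_PARAMS)
        np.testing.assert_allclose(
            d,
            [-0.10389440436930002, -0.3261671169, 0.00019285714285714286],
            atol=1e-15,
        )

    def test_non_finite_state_raises_with_diagnostics(self):
        with pytest.raises(SimulationError) as err:
            rhs(2.5, [np.nan, 0.0, 0.0], SET3_PARAMS)
        assert err.value.t == 2.5


class TestSimulate:
    def test_exponential_limit_mu_only(self):
        p = CoupledTraitParams(mu=0.07)
        init = InitialCondition(0.0, 1.0, 0.5, 0.0)
        traj = simulate(p, init, [0.0, 5.0, 10.0])
        np.testing.assert_allclose(traj.N, np.exp(0.07 * traj.times), atol=1e-7)
        np.testing.assert_allclose(traj.P, 0.5 * np.exp(0.07 * traj.times),
                                   atol=1e-7)

    def test_hyperbolic_decay_alpha_only(self):
        # dN/dt = -alpha*N^2 has closed form N0/(1 + alpha*N0*t)
        p = CoupledTraitParams(alpha=0.5)
        init = InitialCondition(0.0, 1.0, 0.0, 0.0)
        traj = simulate(p, init, [0.0, 2.0, 8.0])
        np.testing.assert_allclose(
            traj.N, 1.0 / (1.0 + 0.5 * traj.times), atol=1e-7
        )
        assert traj.N[1] == pytest.approx(0.5, abs=1e-7)

    def test_exponential_stress_gamma_only(self):
        # with N frozen at N0, E(t) = E0 * exp(gamma*N0/(N0+K)*t)
        p = CoupledTraitParams(gamma=0.03, K=0.5)
        init = InitialCondition(0.0, 0.5, 0.0, 0.01)
        traj = simulate(p, init, [0.0, 10.0])
        assert traj.E_stress[-1] == pytest.approx(
            0.01 * math.exp(0.03 * 0.5 / 1.0 * 10.0), abs=1e-7
        )
        assert traj.E_stress[-1] == pytest.approx(0.0116183, abs=1e-6)

    def test_single_time_equal_to_t0_skips_integration(self):
        init = InitialCondition(3.0, 0.9, 0.93, 0.01)
        traj = simulate(SET3_PARAMS, init, [3.0])
        assert len(traj) == 1
        np.testing.assert_array_equal(traj.states[0], [0.9, 0.93, 0.01])

    def test_first_state_equals_initial_condition(self, set3_init):
        traj = simulate(SET3_PARAMS, set3_init, [0.0, 1.0, 2.0])
        np.testing.assert_array_equal(traj.states[0], set3_init.state)

    def test_grid_granularity_invariance(self, set3_init):
        coarse = simulate(SET3_PARAMS, set3_init, [0.0, 10.0, 23.0])
        fine = simulate(SET3_PARAMS, set3_init, np.linspace(0.0, 23.0, 47))
        idx = [0, 20, 46]
        np.testing.assert_allclose(fine.states[idx][[2]], coarse.states[[2]],
                                   atol=1e-7)

    def test_eval_times_validation(self, set3_init):
        with pytest.raises(InvalidInputError):
            simulate(SET3_PARAMS, set3_init, [0.0, 0.0, 1.0])
        with pytest.raises(InvalidInputError):
            simulate(SET3_PARAMS, set3_init, [-1.0, 1.0])

    def test_blowup_raises_structured_error(self):
        # dN/dt = 10*N over 4 years ends at ~e^40 > 1e12
        p = CoupledTraitParams(mu=10.0)
        init = InitialCondition(0.0, 1.0, 0.0, 0.0)
        with pytest.raises(SimulationError) as err:
            simulate(p, init, [0.0, 4.0])
        assert err.value.t is not None

    def test_agrees_with_fixed_step_rk4_oracle(self, set3_init):
        traj = simulate(SET3_PARAMS, set3_init, [0.0, 25.0])
        expected = rk4_oracle(SET3_PARAMS, set3_init, 25.0, h=1e-3)
        np.testing.assert_allclose(traj.states[-1], expected, atol=1e-6)

    def test_lsoda_agrees_with_rk45_on_benign_points(self, set3_init):
        a = simulate(SET3_PARAMS, set3_init, [0.0, 5.0, 25.0], method="RK45")
        b = simulate(SET3_PARAMS, set3_init, [0.0, 5.0, 25.0], method="LSODA")
        np.testing.assert_allclose(a.states, b.states, atol=1e-6)


nonneg_params = st.builds(
    CoupledTraitParams,
    mu=st.floats(0, 0.3),
    alpha=st.floats(0, 1.0),
    beta=st.floats(0, 1.0),
    gamma=st.floats(0, 0.3),
    c1=st.floats(0, 2.0),
    c2=st.floats(0, 2.0),
    c3=st.floats(0, 2.0),
    K=st.floats(0.1, 2.0),
    G=st.floats(0.5, 2.0),
)


class TestInvariants:
    @given(
        nonneg_params,
        st.floats(0, 1.0), st.floats(0, 1.0), st.floats(0, 0.5),
    )
    @settings(deadline=None, max_examples=25)
    def test_nonnegativity_preserved(self, params, n0, p0, e0):
        init = InitialCondition(0.0, n0, p0, e0)
        traj = simulate(params, init, [0.0, 2.0, 5.0, 10.0])
        assert np.all(traj.states >= -1e-9)

    @given(nonneg_params)
    @settings(deadline=None, max_examples=25)
    def test_stress_nondecreasing(self, params):
        init = InitialCondition(0.0, 0.8, 0.7, 0.05)
        traj = simulate(params, init, np.linspace(0.0, 10.0, 21))
        assert np.all(np.diff(traj.E_stress) >= -1e-9)

    def test_uncoupled_flag_matches_manually_zeroed_coupling(self):
        base = CoupledTraitParams(mu=0.05, alpha=0.2, beta=0.4, gamma=0.1,
                                  c1=1.0, c2=0.3, c3=0.5, K=0.5)
        flagged = CoupledTraitParams(mu=0.05, alpha=0.2, beta=0.4, gamma=0.1,
                                     c1=1.0, c2=0.3, c3=0.5, K=0.5,
                                     coupled=False)
        zeroed = CoupledTraitParams(mu=0.05, alpha=0.2, beta=0.0, gamma=0.1,
                                    c1=1.0, c2=0.0, c3=0.0, K=0.5)
        init = InitialCondition(0.0, 0.8, 0.7, 0.05)
        times = [0.0, 3.0, 9.0]
        np.testing.assert_allclose(
            simulate(flagged, init, times).states,
            simulate(zeroed, init, times).states,
            atol=1e-9,
        )
        # and with beta=c2=c3=0 the coupled and uncoupled systems coincide
        coupled_equiv = CoupledTraitParams(mu=0.05, alpha=0.2, gamma=0.1, K=0.5)
        uncoupled_equiv = CoupledTraitParams(mu=0.05, alpha=0.2, gamma=0.1,
                                             K=0.5, coupled=False)
        np.testing.assert_allclose(
            simulate(coupled_equiv, init, times).states,
            simulate(uncoupled_equiv, init, times).states,
            atol=1e-9,
        )

    def test_invalid_capacity_constants_rejected(self):
        with pytest.raises(InvalidInputError):
            CoupledTraitParams(K=0.0)
        with pytest.raises(InvalidInputError):
            CoupledTraitParams(G=-1.0)
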