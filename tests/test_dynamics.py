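"""Core dynamics: rate functions, derivatives, integration, steady states.

Hand-derived expected values come from evaluating the Liebig/clamping
expressions directly; integration checks use the closed-form plant-free
solution, the exact nitrogen conservation law, and an independent
fixed-step fourth-order integrator.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nfixclim.dynamics import (
    EcosystemState,
    Trajectory,
    derivatives,
    fixation_rate,
    fixation_summary,
    growth_rate_fixer,
    growth_rate_nonfixer,
    nitrogen_balance_residual,
    simulate,
    steady_state,
    _rhs,
)
from nfixclim.params import FixationStrategy, ParameterSet

from test_params import make_params


class TestFixationRate:
    def test_obligate_pinned_at_constant_rate(self):
        p = make_params()
        strat = FixationStrategy.obligate(7e-4)
        for A, B in [(0.0, 0.0), (5.0, 1e4), (500.0, 2e5)]:
            assert fixation_rate(A, B, p, strat) == pytest.approx(7e-4)

    def test_facultative_shuts_off_when_demand_met(self):
        # large A makes the demand term negative -> clamped at F_min = 0
        p = make_params()
        strat = FixationStrategy.facultative(2e-3)
        assert fixation_rate(1e4, 1e4, p, strat) == 0.0

    def test_incomplete_regulator_floor(self):
        # demand evaluates to 3e-4 (= beta_F/(omega_F(1+gamma_F B)) - nu_F A
        # with beta_F=1, omega_F=500, gamma_F=1e-4, B=10000, nu_F A = 7e-4)
        # which sits below F_min = 5e-4 -> floored
        p = make_params(beta_F=1.0, omega_F=500.0, gamma_F=1e-4, nu_F=7e-5)
        strat = FixationStrategy.incomplete_regulator(5e-4, 2e-3)
        assert fixation_rate(10.0, 10000.0, p, strat) == pytest.approx(5e-4)

    def test_none_strategy_returns_zero(self):
        assert fixation_rate(1.0, 1.0, make_params(), FixationStrategy.none()) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fixation_rate(-1.0, 0.0, make_params(), FixationStrategy.obligate(1e-3))

    @given(
        A=st.floats(0.0, 500.0),
        B=st.floats(0.0, 3e5),
        fmax=st.floats(1e-5, 5e-3),
        fmin_frac=st.floats(0.01, 0.99),
    )
    def test_strategy_nesting(self, A, B, fmax, fmin_frac):
        """Pointwise F ordering forced by the clamping: obligate >=
        incomplete regulator >= facultative at identical (A, B, F_max)."""
        p = make_params()
        f_ob = fixation_rate(A, B, p, FixationStrategy.obligate(fmax))
        f_inc = fixation_rate(
            A, B, p, FixationStrategy.incomplete_regulator(fmin_frac * fmax, fmax)
        )
        f_fac = fixation_rate(A, B, p, FixationStrategy.facultative(fmax))
        assert f_ob >= f_inc >= f_fac >= 0.0
        assert f_ob == pytest.approx(fmax)


class TestGrowthRates:
    def test_fixer_hand_value(self):
        # MIN[500*(1e-5*100 + 0), 1/(1+0)] = MIN[0.5, 1] = 0.5
        p = make_params(omega_F=500.0, nu_F=1e-5, beta_F=1.0, gamma_F=1e-4)
        assert growth_rate_fixer(100.0, 0.0, 0.0, p, 0.0) == pytest.approx(0.5)

    def test_fixer_limits(self):
        p = make_params()
        assert growth_rate_fixer(0.0, 10.0, 10.0, p, 0.0) == 0.0
        dense = p.beta_F / (1.0 + p.gamma_F * 2e4)
        assert growth_rate_fixer(1e9, 1e4, 1e4, p, 0.0) == pytest.approx(dense)

    def test_nonfixer_hand_value(self):
        # MIN[500*1e-5*50, 1/(1+1)] = MIN[0.25, 0.5] = 0.25
        p = make_params(omega_0=500.0, nu_0=1e-5, beta_0=1.0, gamma_0=1e-4)
        assert growth_rate_nonfixer(50.0, 0.0, 10000.0, p) == pytest.approx(0.25)

    def test_nonfixer_limits(self):
        p = make_params()
        assert growth_rate_nonfixer(0.0, 0.0, 0.0, p) == 0.0
        dense = p.beta_0 / (1.0 + p.gamma_0 * 2e4)
        assert growth_rate_nonfixer(1e9, 1e4, 1e4, p) == pytest.approx(dense)


class TestDerivatives:
    def test_empty_system_only_deposition(self):
        p = make_params(I=3.0)
        state = EcosystemState(B_F=0, B_0=0, D=0, A=0, E=0)
        assert derivatives(state, p, FixationStrategy.obligate(1e-3)) == (0, 0, 0, 3.0, 0)

    def test_plant_free_steady_state(self):
        p = make_params()
        A = p.I / (p.k + p.eta)
        state = EcosystemState(B_F=0, B_0=0, D=0, A=A, E=p.eta * A / p.psi)
        dy = derivatives(state, p, FixationStrategy.none())
        assert np.allclose(dy, 0.0, atol=1e-12)

    def test_none_strategy_freezes_fixer_pool(self):
        p = make_params()
        state = EcosystemState(B_F=500.0, B_0=100.0, D=10.0, A=5.0, E=0.0)
        dy = derivatives(state, p, FixationStrategy.none())
        assert dy[0] == 0.0

    @given(
        B_F=st.floats(0.0, 2e5), B_0=st.floats(0.0, 2e5),
        D=st.floats(0.0, 500.0), A=st.floats(0.0, 200.0),
    )
    def test_nitrogen_balance_identity(self, B_F, B_0, D, A):
        """Summing the pool equations in N units reproduces the exact
        external balance I + F*B_F - (k+eta)*A - phi*D at any state."""
        p = make_params()
        strat = FixationStrategy.incomplete_regulator(5e-4, 1.5e-3)
        dB_F, dB_0, dD, dA, _ = _rhs(np.array([B_F, B_0, D, A, 0.0]), p, strat)
        lhs = dD + dA + dB_F / p.omega_F + dB_0 / p.omega_0
        F = fixation_rate(A, B_F + B_0, p, strat)
        rhs = p.I + F * B_F - (p.k + p.eta) * A - p.phi * D
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-9)

    def test_nan_state_rejected(self):
        with pytest.raises(ValueError):
            EcosystemState(B_F=float("nan"), B_0=0, D=0, A=0)


class TestSimulate:
    def test_plant_free_closed_form(self):
        """With no plants the available-N pool follows
        A(t) = (I/(k+eta)) (1 - exp(-(k+eta) t)) exactly."""
        p = make_params()
        traj = simulate(EcosystemState(0, 0, 0, 0, 0), p, FixationStrategy.none())
        rate = p.k + p.eta
        expected = p.I / rate * (1.0 - np.exp(-rate * traj.t))
        rel = np.abs(traj.A[1:] - expected[1:]) / expected[1:]
        assert rel.max() < 1e-6

    def test_output_grid_contract(self):
        p = make_params()
        initial = EcosystemState(10, 10, 20, 1, 0)
        traj = simulate(initial, p, FixationStrategy.obligate(1e-3),
                        horizon=10.0, output_step=0.5)
        assert len(traj.t) == 21
        assert traj.t[0] == 0.0 and traj.t[-1] == 10.0
        assert traj.initial.as_array() == pytest.approx(initial.as_array())

    def test_pools_stay_nonnegative(self):
        p = make_params()
        traj = simulate(EcosystemState(10, 10, 20, 1, 0), p,
                        FixationStrategy.facultative(1.5e-3))
        for pool in (traj.B_F, traj.B_0, traj.D, traj.A, traj.E):
            assert pool.min() >= 0.0

    def test_facultative_downregulates_under_high_deposition(self):
        """Under heavy deposition the facultative fixer shuts fixation
        off and the community converges toward the non-fixer one."""
        p = make_params(I=11.0)
        initial = EcosystemState(10, 10, 20, 1, 0)
        fac = simulate(initial, p, FixationStrategy.facultative(1.5e-3))
        assert fac.fixation_flux[-1] == pytest.approx(0.0, abs=1e-9)
        assert fixation_summary(fac)[0] < 0.15  # mean flux ~ 0 kg N/ha/yr
        non = simulate(EcosystemState(0, 10, 20, 1, 0), p, FixationStrategy.none())
        assert fac.total_biomass[-1] == pytest.approx(non.total_biomass[-1], rel=0.02)

    def test_invalid_horizon_rejected(self):
        with pytest.raises(ValueError):
            simulate(EcosystemState(0, 0, 0, 0, 0), make_params(),
                     FixationStrategy.none(), horizon=-1.0)

    def test_fixed_step_rk4_oracle(self):
        """An independent fixed-step 4th-order integrator at small step
        agrees with the adaptive solver on every pool."""
        p = make_params()
        strat = FixationStrategy.obligate(1.8e-3)
        initial = EcosystemState(10, 10, 20, 1, 0)
        traj = simulate(initial, p, strat, horizon=40.0, output_step=0.5)

        h = 0.005
        y = initial.as_array()
        recorded = [y.copy()]
        steps_per_out = int(round(0.5 / h))
        for _ in range(80):
            for _ in range(steps_per_out):
                k1 = _rhs(y, p, strat)
                k2 = _rhs(y + 0.5 * h * k1, p, strat)
                k3 = _rhs(y + 0.5 * h * k2, p, strat)
                k4 = _rhs(y + h * k3, p, strat)
                y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            recorded.append(y.copy())
        oracle = np.array(recorded).T
        pools = np.vstack([traj.B_F, traj.B_0, traj.D, traj.A, traj.E])
        scale = np.abs(oracle).max(axis=1) + 1e-12
        rel = np.abs(pools - oracle).max(axis=1) / scale
        assert rel.max() < 1e-4


class TestNitrogenBalance:
    def test_residual_small_on_simulated_trajectory(self):
        p = make_params()
        traj = simulate(EcosystemState(10, 10, 20, 1, 0), p,
                        FixationStrategy.obligate(1.5e-3))
        n0 = traj.D[0] + traj.A[0] + traj.B_F[0] / p.omega_F + traj.B_0[0] / p.omega_0
        assert np.abs(nitrogen_balance_residual(traj)).max() < 1e-6 * (n0 + 1.0)

    def test_zero_flux_static_state(self):
        """A trajectory pinned at the plant-free equilibrium has zero
        residual identically (trapezoid fallback path)."""
        p = make_params()
        t = np.linspace(0, 10, 11)
        A = np.full_like(t, p.I / (p.k + p.eta))
        z = np.zeros_like(t)
        traj = Trajectory(t=t, B_F=z, B_0=z, D=z, A=A, E=p.eta * A / p.psi + z,
                          F=z, fixation_flux=z, params=p,
                          strategy=FixationStrategy.none())
        assert np.abs(nitrogen_balance_residual(traj)).max() < 1e-12

    def test_corrupted_trajectory_detected(self):
        p = make_params()
        traj = simulate(EcosystemState(10, 10, 20, 1, 0), p,
                        FixationStrategy.obligate(1.5e-3))
        corrupted = Trajectory(
            t=traj.t, B_F=traj.B_F, B_0=traj.B_0, D=traj.D, A=traj.A + 1.0,
            E=traj.E, F=traj.F, fixation_flux=traj.fixation_flux,
            params=p, strategy=traj.strategy,
        )
        assert np.abs(nitrogen_balance_residual(corrupted)).max() > 0.5


class TestFixationSummary:
    def test_nonfixer_is_zero(self):
        p = make_params()
        traj = simulate(EcosystemState(0, 10, 20, 1, 0), p, FixationStrategy.none())
        assert fixation_summary(traj) == (0.0, 0.0, 0.0)

    def test_constant_flux(self):
        p = make_params()
        t = np.linspace(0, 100, 1001)
        ones = np.ones_like(t)
        traj = Trajectory(t=t, B_F=1000 * ones, B_0=0 * ones, D=0 * ones,
                          A=0 * ones, E=0 * ones, F=5e-3 * ones,
                          fixation_flux=5.0 * ones, params=p,
                          strategy=FixationStrategy.obligate(5e-3))
        mean, lo, hi = fixation_summary(traj)
        assert (mean, lo, hi) == (pytest.approx(5.0), 5.0, 5.0)


class TestSteadyState:
    def test_plant_free_branch(self):
        p = make_params()
        ss = steady_state(p, FixationStrategy.none(),
                          initial_guess=EcosystemState(0, 0, 0, 0, 0))
        assert ss.state.A == pytest.approx(p.I / (p.k + p.eta), rel=1e-8)
        assert ss.state.D == pytest.approx(0.0, abs=1e-8)
        assert ss.state.E == pytest.approx(p.eta * ss.state.A / p.psi, rel=1e-8)
        assert ss.fixer_branch == "absent"

    def test_residual_below_tolerance_and_branch_reported(self):
        p = make_params()
        ss = steady_state(p, FixationStrategy.obligate(1.8e-3))
        scale = max(ss.state.as_array().max(), 1.0)
        assert ss.residual < 1e-7 * scale
        assert ss.nonfixer_branch in ("n_limited", "density_limited")

    def test_density_limited_equilibrium_matches_analytic_value(self):
        """When the non-fixer equilibrium sits on the density-dependent
        branch, total biomass equals (beta_0/mu_0 - 1)/gamma_0."""
        p = make_params()
        ss = steady_state(p, FixationStrategy.obligate(1.8e-3))
        analytic = (p.beta_0 / p.mu_0 - 1.0) / p.gamma_0
        assert ss.nonfixer_branch == "density_limited"
        assert ss.total_biomass == pytest.approx(analytic, rel=1e-6)
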