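"""Greenhouse-gas accounting: GWP arithmetic, radiative-forcing
quadratures against closed-form oracles, and effect combination."""

import numpy as np
import pytest

from nfixclim.dynamics import Trajectory
from nfixclim.effects import (
    co2_effect_gwp,
    co2_effect_rf,
    n2o_effect_gwp,
    n2o_effect_rf,
    net_effect,
    radiative_efficiency,
    relative_effect,
    to_c_equivalents,
)
from nfixclim.params import FixationStrategy, RadiativeConstants

from test_params import make_params

H = 100.0


def make_traj(t=None, B_0=None, A=None, E=None, params=None):
    """Synthetic trajectory with prescribed pool time series."""
    t = np.linspace(0.0, H, 1001) if t is None else t
    z = np.zeros_like(t)
    return Trajectory(
        t=t,
        B_F=z,
        B_0=z if B_0 is None else B_0,
        D=z,
        A=z if A is None else A,
        E=z if E is None else E,
        F=z,
        fixation_flux=z,
        params=params or make_params(),
        strategy=FixationStrategy.none(),
    )


class TestGwpMethod:
    @pytest.mark.parametrize("delta_b,expected", [
        (124_000.0, -4546.666667),   # biomass gain -> cooling
        (0.0, 0.0),
        (-12_000.0, 440.0),          # biomass loss -> warming
    ])
    def test_co2_effect_arithmetic(self, delta_b, expected):
        t = np.linspace(0.0, H, 1001)
        traj = make_traj(t=t, B_0=np.linspace(0.0, max(delta_b, 0.0), 1001)
                         if delta_b >= 0 else np.linspace(-delta_b, 0.0, 1001))
        assert co2_effect_gwp(traj) == pytest.approx(expected, rel=1e-9)

    def test_n2o_effect_arithmetic(self):
        # dE = 1 kg N2O-N/ha over 100 yr -> 0.01 * 44/28 * 298
        t = np.linspace(0.0, H, 1001)
        traj = make_traj(t=t, E=np.linspace(0.0, 1.0, 1001))
        assert n2o_effect_gwp(traj) == pytest.approx(4.682857, rel=1e-6)

    def test_linearity(self):
        t = np.linspace(0.0, H, 1001)
        one = n2o_effect_gwp(make_traj(t=t, E=np.linspace(0, 1, 1001)))
        two = n2o_effect_gwp(make_traj(t=t, E=np.linspace(0, 2, 1001)))
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_wrong_horizon_rejected(self):
        t = np.linspace(0.0, 50.0, 501)
        with pytest.raises(ValueError, match="100"):
            co2_effect_gwp(make_traj(t=t))


class TestRadiativeEfficiency:
    def test_scales_linearly_in_re_ppbv(self):
        c1 = RadiativeConstants()
        c2 = RadiativeConstants(re_n2o_ppbv=2 * c1.re_n2o_ppbv)
        assert radiative_efficiency(c2, "n2o") == pytest.approx(
            2 * radiative_efficiency(c1, "n2o")
        )

    def test_ar5_n2o_hand_value(self):
        # 3.03e-3 * (28.97/44.013) * 1e9 / 5.135e18, evaluated by hand
        assert radiative_efficiency(RadiativeConstants(), "n2o") == pytest.approx(
            3.884e-13, rel=1e-3
        )

    def test_identity_construction(self):
        c = RadiativeConstants(re_co2_ppbv=5.135e9, M_CO2=28.97)
        assert radiative_efficiency(c, "co2") == pytest.approx(1.0, rel=1e-12)

    def test_unknown_gas(self):
        with pytest.raises(ValueError, match="ch4"):
            radiative_efficiency(RadiativeConstants(), "ch4")


class TestRadiativeForcingMethod:
    def test_zero_biomass_change_gives_zero(self):
        assert co2_effect_rf(make_traj()) == 0.0
        assert n2o_effect_rf(make_traj()) == 0.0

    def test_sign_opposes_biomass_change(self):
        t = np.linspace(0.0, H, 1001)
        grow = make_traj(t=t, B_0=100.0 * t)
        shrink = make_traj(t=t, B_0=1e4 - 100.0 * t)
        assert co2_effect_rf(grow) < 0 < co2_effect_rf(shrink)

    def test_constant_sequestration_flux_closed_form(self):
        """Constant biomass growth: the double integral reduces to the
        analytic time-integral of the impulse-response kernel."""
        consts = RadiativeConstants()
        c = 120.0  # kg C/ha/yr
        t = np.linspace(0.0, H, 1001)
        traj = make_traj(t=t, B_0=c * t)
        re = radiative_efficiency(consts, "co2")
        inner = consts.a_0 * H**2 / 2 + sum(
            a_i * tau_i * (H - tau_i * (1.0 - np.exp(-H / tau_i)))
            for a_i, tau_i in zip((consts.a_1, consts.a_2, consts.a_3), consts.tau)
        )
        oracle = -re * (c * 44.0 / 12.0) * inner
        assert co2_effect_rf(traj, consts) == pytest.approx(oracle, rel=1e-6)

    def test_constant_available_n_closed_form(self):
        consts = RadiativeConstants()
        p = make_params()
        cA = 30.0
        traj = make_traj(A=np.full(1001, cA), params=p)
        re = radiative_efficiency(consts, "n2o")
        oracle = (
            re * p.eta * cA * (44.0 / 28.0) / p.psi
            * (H - (1.0 - np.exp(-p.psi * H)) / p.psi)
        )
        assert n2o_effect_rf(traj, consts) == pytest.approx(oracle, rel=1e-6)

    def test_quadrature_converges_under_grid_refinement(self):
        p = make_params()
        results = []
        for n in (1001, 2001):
            t = np.linspace(0.0, H, n)
            B = 5e4 * (1.0 - np.exp(-0.05 * t))
            A = 20.0 * (1.0 - np.exp(-0.1 * t))
            traj = make_traj(t=t, B_0=B, A=A, params=p)
            results.append((co2_effect_rf(traj), n2o_effect_rf(traj)))
        for coarse, fine in zip(*results):
            pass
        (co2_c, n2o_c), (co2_f, n2o_f) = results
        assert abs(co2_c - co2_f) / abs(co2_f) < 1e-4
        assert abs(n2o_c - n2o_f) / abs(n2o_f) < 1e-4


class TestCombination:
    @pytest.mark.parametrize("co2,n2o,expected,warming", [
        (-100.0, 30.0, -70.0, False),
        (0.0, 0.0, 0.0, False),
        (-30.0, 100.0, 70.0, True),
    ])
    def test_net_effect(self, co2, n2o, expected, warming):
        result = net_effect(co2, n2o)
        assert result.net_effect == pytest.approx(expected)
        assert result.is_warming is warming

    def test_relative_effect_identity_and_antisymmetry(self):
        x = net_effect(-100.0, 30.0)
        y = net_effect(-40.0, 5.0)
        assert relative_effect(x, x).net_effect == 0.0
        fwd = relative_effect(x, y)
        rev = relative_effect(y, x)
        assert fwd.co2_effect == -rev.co2_effect
        assert fwd.n2o_effect == -rev.n2o_effect

    def test_method_mismatch_rejected(self):
        gwp = net_effect(-1.0, 0.0, "gwp")
        rf = net_effect(-1.0, 0.0, "radiative_forcing")
        with pytest.raises(ValueError, match="mismatch"):
            relative_effect(gwp, rf)

    @pytest.mark.parametrize("value,expected", [(44.0, 12.0), (0.0, 0.0),
                                                (-4546.666667, -1240.0)])
    def test_to_c_equivalents(self, value, expected):
        assert to_c_equivalents(value) == pytest.approx(expected, rel=1e-9)
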