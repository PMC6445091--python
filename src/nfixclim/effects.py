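"""Greenhouse-gas accounting: CO2 effects, N2O effects and their sum.

Two complementary accounting methods convert a 100-year ecosystem
trajectory into a common climate currency (negative = cooling):

* **GWP method** ("gwp") — the 100-yr change in total biomass C and in
  the atmospheric N2O pool, averaged per year, with N2O converted to
  CO2 equivalents through its 100-yr global warming potential
  (298 kg CO2 per kg N2O).  Units: kg CO2(-eq) ha^-1 yr^-1.
* **Radiative-forcing method** ("radiative_forcing") — cumulative
  radiative forcing of the continuous CO2 sequestration flux and of the
  continuous soil N2O emission flux over the same window, built from the
  multi-exponential atmospheric CO2 impulse response and the first-order
  N2O decay.  Units: W m^-2 yr per hectare's flux.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory
from .params import ParameterSet, RadiativeConstants

__all__ = [
    "EffectResult",
    "co2_effect_gwp",
    "n2o_effect_gwp",
    "co2_effect_rf",
    "n2o_effect_rf",
    "radiative_efficiency",
    "net_effect",
    "relative_effect",
    "to_c_equivalents",
    "CO2_PER_C",
    "N2O_PER_N",
]

CO2_PER_C = 44.0 / 12.0     # kg CO2 per kg C
N2O_PER_N = 44.0 / 28.0     # kg N2O per kg N2O-N
HORIZON = 100.0             # accounting window, yr

_UNITS = {
    "gwp": "kg CO2-eq ha-1 yr-1",
    "radiative_forcing": "W m-2 yr (per ha flux)",
}


@dataclass(frozen=True)
class EffectResult:
    """CO2 effect, N2O effect and their sum under one accounting method."""

    co2_effect: float
    n2o_effect: float
    method: str
    units: str

    def __post_init__(self) -> None:
        if self.method not in _UNITS:
            raise ValueError(f"unknown accounting method {self.method!r}")

    @property
    def net_effect(self) -> float:
        return self.co2_effect + self.n2o_effect

    @property
    def is_warming(self) -> bool:
        return self.net_effect > 0.0


def _check_horizon(traj: Trajectory) -> None:
    if abs(traj.horizon - HORIZON) > 1e-9:
        raise ValueError(
            f"accounting methods are defined for a {HORIZON:.0f}-yr window; "
            f"trajectory spans {traj.horizon:g} yr"
        )


# ---------------------------------------------------------------------------
# method 1: pool changes + global warming potential
# ---------------------------------------------------------------------------

def co2_effect_gwp(traj: Trajectory) -> float:
    """CO2 effect (kg CO2 ha^-1 yr^-1): minus the 100-yr mean rate of
    total biomass C change, converted to CO2 mass."""
    _check_horizon(traj)
    delta_b = traj.total_biomass[-1] - traj.total_biomass[0]
    return -delta_b / HORIZON * CO2_PER_C


def n2o_effect_gwp(traj: Trajectory, consts: RadiativeConstants | None = None) -> float:
    """N2O effect (kg CO2-eq ha^-1 yr^-1): the 100-yr mean rate of change
    of the atmospheric N2O pool times GWP-100 of N2O."""
    _check_horizon(traj)
    consts = consts or RadiativeConstants()
    delta_e = traj.E[-1] - traj.E[0]
    return delta_e / HORIZON * N2O_PER_N * consts.gwp_n2o


# ---------------------------------------------------------------------------
# method 2: cumulative radiative forcing of continuous fluxes
# ---------------------------------------------------------------------------

def radiative_efficiency(consts: RadiativeConstants, gas: str) -> float:
    """Convert radiative efficiency from W m^-2 ppbv^-1 to W m^-2 kg^-1:
    RE_ppbv * (M_air / M_gas) * 1e9 / T_M."""
    if gas == "co2":
        re_ppbv, molar = consts.re_co2_ppbv, consts.M_CO2
    elif gas == "n2o":
        re_ppbv, molar = consts.re_n2o_ppbv, consts.M_N2O
    else:
        raise ValueError(f"unknown gas {gas!r} (expected 'co2' or 'n2o')")
    return re_ppbv * (consts.M_A / molar) * 1e9 / consts.T_M


def co2_response_integral(t_remaining: np.ndarray, consts: RadiativeConstants) -> np.ndarray:
    """Time-integrated airborne fraction of a CO2 pulse over ``t_remaining``
    years: (t a_0 + sum_i a_i tau_i (1 - exp(-t/tau_i)))."""
    t = np.asarray(t_remaining, dtype=float)
    out = t * consts.a_0
    for a_i, tau_i in zip((consts.a_1, consts.a_2, consts.a_3), consts.tau):
        out = out + a_i * tau_i * (1.0 - np.exp(-t / tau_i))
    return out


def co2_effect_rf(traj: Trajectory, consts: RadiativeConstants | None = None) -> float:
    """Cumulative radiative forcing of the continuous CO2 sequestration
    flux (negative = cooling).

    The sequestration flux at emission time t_E is the instantaneous
    rate of total-biomass-C change (finite differences on the output
    grid) converted to CO2 mass; each increment forces the atmosphere
    for the remaining (100 - t_E) years through the impulse-response
    integral.  Quadrature: composite trapezoid on the output grid.
    """
    _check_horizon(traj)
    consts = consts or RadiativeConstants()
    g_co2 = np.gradient(traj.total_biomass, traj.t) * CO2_PER_C  # kg CO2/ha/yr
    weight = co2_response_integral(HORIZON - traj.t, consts)
    re = radiative_efficiency(consts, "co2")
    return float(-np.trapezoid(re * g_co2 * weight, traj.t))


def n2o_effect_rf(
    traj: Trajectory,
    consts: RadiativeConstants | None = None,
    params: ParameterSet | None = None,
) -> float:
    """Cumulative radiative forcing of the continuous soil N2O emission
    flux eta*A(t_E), each increment decaying at the atmospheric removal
    rate psi over the remaining window."""
    _check_horizon(traj)
    consts = consts or RadiativeConstants()
    p = params if params is not None else traj.params
    re = radiative_efficiency(consts, "n2o")
    emission_n2o = p.eta * traj.A * N2O_PER_N  # kg N2O/ha/yr
    weight = (1.0 - np.exp(-p.psi * (HORIZON - traj.t))) / p.psi
    return float(np.trapezoid(re * emission_n2o * weight, traj.t))


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------

def net_effect(co2: float, n2o: float, method: str = "gwp") -> EffectResult:
    """Bundle a CO2 effect and an N2O effect computed under the same
    method into an EffectResult (net = sum; negative = cooling)."""
    return EffectResult(
        co2_effect=float(co2),
        n2o_effect=float(n2o),
        method=method,
        units=_UNITS[method],
    )


def effects_for(
    traj: Trajectory,
    method: str = "gwp",
    consts: RadiativeConstants | None = None,
) -> EffectResult:
    """Compute both effect components of a trajectory under one method."""
    if method == "gwp":
        return net_effect(co2_effect_gwp(traj), n2o_effect_gwp(traj, consts), "gwp")
    if method == "radiative_forcing":
        return net_effect(
            co2_effect_rf(traj, consts),
            n2o_effect_rf(traj, consts),
            "radiative_forcing",
        )
    raise ValueError(f"unknown accounting method {method!r}")


def relative_effect(with_fixer: EffectResult, nonfixer_only: EffectResult) -> EffectResult:
    """Componentwise difference (with-fixer minus non-fixer): the net
    CO2-N2O effect attributed to the N-fixing trees."""
    if with_fixer.method != nonfixer_only.method or with_fixer.units != nonfixer_only.units:
        raise ValueError(
            f"cannot difference effects with mismatched method/units: "
            f"{with_fixer.method}/{with_fixer.units} vs "
            f"{nonfixer_only.method}/{nonfixer_only.units}"
        )
    return EffectResult(
        co2_effect=with_fixer.co2_effect - nonfixer_only.co2_effect,
        n2o_effect=with_fixer.n2o_effect - nonfixer_only.n2o_effect,
        method=with_fixer.method,
        units=with_fixer.units,
    )


def to_c_equivalents(value_co2_eq: float) -> float:
    """Re-express a CO2-equivalent quantity in C radiative equivalents
    (multiply by 12/44)."""
    return value_co2_eq / CO2_PER_C
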