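"""State space, dynamics and integration of the ecosystem model.

Five pools are tracked per hectare: fixer biomass carbon ``B_F``,
non-fixer biomass carbon ``B_0`` (kg C/ha), plant-unavailable soil
nitrogen ``D`` (detritus), plant-available soil nitrogen ``A``
(kg N/ha), and the atmospheric N2O burden ``E`` (kg N2O-N/ha) fed by
soil emissions ``eta * A`` and removed at rate ``psi``.

Growth follows Liebig's law of the minimum: the realized per-capita
growth rate is the smaller of an N-limited rate (proportional to N
uptake plus, for fixers, fixation) and a density-dependent rate that
stands in for limitation by light, phosphorus or space.  Fixation per
unit biomass carbon tracks the fixer's unmet N demand, clamped to the
strategy's ``[F_min, F_max]`` interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import FixationStrategy, ParameterSet

__all__ = [
    "EcosystemState",
    "Trajectory",
    "SteadyState",
    "IntegrationError",
    "fixation_rate",
    "growth_rate_fixer",
    "growth_rate_nonfixer",
    "derivatives",
    "simulate",
    "steady_state",
    "nitrogen_balance_residual",
    "fixation_summary",
]

#: Pools may undershoot zero by at most this much before the run aborts.
NEGATIVE_POOL_TOLERANCE = 1e-8


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or produces an invalid trajectory."""


@dataclass(frozen=True)
class EcosystemState:
    """The five model pools at one instant."""

    B_F: float  # fixer biomass, kg C/ha
    B_0: float  # non-fixer biomass, kg C/ha
    D: float    # plant-unavailable soil N, kg N/ha
    A: float    # plant-available soil N, kg N/ha
    E: float = 0.0  # atmospheric N2O pool, kg N2O-N/ha
    t: float = 0.0  # time, yr

    def __post_init__(self) -> None:
        for name in ("B_F", "B_0", "D", "A", "E"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0.0:
                raise ValueError(f"pool {name!r} must be finite and >= 0, got {value!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.B_F, self.B_0, self.D, self.A, self.E], dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """A simulated trajectory on a regular output grid.

    Besides the five pools, the realized fixation rate per unit biomass
    C (``F``) and the ecosystem-scale fixation flux ``F * B_F``
    (kg N/ha/yr) are stored per step, together with the cumulative net
    nitrogen flux integrated alongside the state (used by the
    mass-balance diagnostic).
    """

    t: np.ndarray
    B_F: np.ndarray
    B_0: np.ndarray
    D: np.ndarray
    A: np.ndarray
    E: np.ndarray
    F: np.ndarray
    fixation_flux: np.ndarray
    params: ParameterSet
    strategy: FixationStrategy
    cumulative_n_flux: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    # -- accessors ---------------------------------------------------------
    @property
    def horizon(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def total_biomass(self) -> np.ndarray:
        return self.B_F + self.B_0

    @property
    def n2o_emission(self) -> np.ndarray:
        """Instantaneous soil N2O emission, kg N2O-N/ha/yr."""
        return self.params.eta * self.A

    def state_at(self, index: int) -> EcosystemState:
        return EcosystemState(
            B_F=max(float(self.B_F[index]), 0.0),
            B_0=max(float(self.B_0[index]), 0.0),
            D=max(float(self.D[index]), 0.0),
            A=max(float(self.A[index]), 0.0),
            E=max(float(self.E[index]), 0.0),
            t=float(self.t[index]),
        )

    @property
    def initial(self) -> EcosystemState:
        return self.state_at(0)

    @property
    def final(self) -> EcosystemState:
        return self.state_at(-1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "B_F": self.B_F,
                "B_0": self.B_0,
                "D": self.D,
                "A": self.A,
                "E": self.E,
                "F": self.F,
                "fixation_flux": self.fixation_flux,
            }
        )


@dataclass(frozen=True)
class SteadyState:
    """An equilibrium of the model with diagnostic information."""

    state: EcosystemState
    residual: float
    fixer_branch: str      # "n_limited" | "density_limited" | "absent"
    nonfixer_branch: str
    F: float               # realized fixation rate per unit biomass C

    @property
    def total_biomass(self) -> float:
        return self.state.B_F + self.state.B_0


# ---------------------------------------------------------------------------
# pointwise rate functions
# ---------------------------------------------------------------------------

def fixation_rate(
    A: float,
    B_total: float,
    params: ParameterSet,
    strategy: FixationStrategy,
) -> float:
    """N fixation rate per unit biomass C (kg N per kg C per yr).

    The unclamped rate is the fixer's N demand at the density-limited
    growth rate minus what soil N uptake already supplies,
    ``beta_F / (omega_F (1 + gamma_F B_total)) - nu_F A``; the realized
    rate is clamped to ``[F_min, F_max]``.
    """
    if A < 0.0 or B_total < 0.0:
        raise ValueError("A and B_total must be non-negative")
    if strategy.kind == "none":
        return 0.0
    demand = params.beta_F / (params.omega_F * (1.0 + params.gamma_F * B_total)) \
        - params.nu_F * A
    return max(strategy.F_min, min(demand, strategy.F_max))


def growth_rate_fixer(
    A: float,
    B_F: float,
    B_0: float,
    params: ParameterSet,
    F: float,
) -> float:
    """Per-capita growth rate of the fixer pool (1/yr), Liebig minimum of
    the N-limited rate ``omega_F (nu_F A + F)`` and the density-dependent
    rate ``beta_F / (1 + gamma_F (B_F + B_0))``."""
    if min(A, B_F, B_0, F) < 0.0:
        raise ValueError("inputs must be non-negative")
    n_limited = params.omega_F * (params.nu_F * A + F)
    density = params.beta_F / (1.0 + params.gamma_F * (B_F + B_0))
    return min(n_limited, density)


def growth_rate_nonfixer(
    A: float,
    B_F: float,
    B_0: float,
    params: ParameterSet,
) -> float:
    """Per-capita growth rate of the non-fixer pool (1/yr)."""
    if min(A, B_F, B_0) < 0.0:
        raise ValueError("inputs must be non-negative")
    n_limited = params.omega_0 * params.nu_0 * A
    density = params.beta_0 / (1.0 + params.gamma_0 * (B_F + B_0))
    return min(n_limited, density)


def _rhs(y: np.ndarray, params: ParameterSet, strategy: FixationStrategy) -> np.ndarray:
    """Right-hand side on the raw 5-vector (B_F, B_0, D, A, E).

    Solver trial states may dip marginally below zero; fluxes are
    evaluated on values floored at zero so the kinked MIN/MAX terms stay
    well defined.
    """
    B_F = max(y[0], 0.0)
    B_0 = max(y[1], 0.0)
    D = max(y[2], 0.0)
    A = max(y[3], 0.0)
    E = max(y[4], 0.0)
    p = params

    if strategy.kind == "none":
        B_F = 0.0
        F = 0.0
        g_F = 0.0
        dB_F = 0.0
    else:
        F = fixation_rate(A, B_F + B_0, p, strategy)
        g_F = growth_rate_fixer(A, B_F, B_0, p, F)
        dB_F = B_F * (g_F - p.mu_F)

    g_0 = growth_rate_nonfixer(A, B_F, B_0, p)
    dB_0 = B_0 * (g_0 - p.mu_0)
    dD = p.mu_F / p.omega_F * B_F + p.mu_0 / p.omega_0 * B_0 - (p.m + p.phi) * D
    dA = (
        p.I
        - p.k * A
        + p.m * D
        - B_F * (g_F - p.omega_F * F) / p.omega_F
        - B_0 * g_0 / p.omega_0
        - p.eta * A
    )
    dE = p.eta * A - p.psi * E
    return np.array([dB_F, dB_0, dD, dA, dE])


def derivatives(
    state: EcosystemState,
    params: ParameterSet,
    strategy: FixationStrategy,
) -> tuple[float, float, float, float, float]:
    """Rates of change of (B_F, B_0, D, A, E) at ``state`` (per yr)."""
    dy = _rhs(state.as_array(), params, strategy)
    return tuple(float(v) for v in dy)


def _net_n_flux(y: np.ndarray, params: ParameterSet, strategy: FixationStrategy) -> float:
    """Net external N flux I + F*B_F - (k + eta)*A - phi*D (kg N/ha/yr)."""
    B_F = max(y[0], 0.0) if strategy.kind != "none" else 0.0
    B_0 = max(y[1], 0.0)
    D = max(y[2], 0.0)
    A = max(y[3], 0.0)
    p = params
    F = fixation_rate(A, B_F + B_0, p, strategy) if strategy.kind != "none" else 0.0
    return p.I + F * B_F - (p.k + p.eta) * A - p.phi * D


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def simulate(
    initial: EcosystemState,
    params: ParameterSet,
    strategy: FixationStrategy,
    horizon: float = 100.0,
    output_step: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_step: float = 0.1,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model over ``[0, horizon]`` years.

    The Liebig MIN/MAX switches leave the right-hand side continuous
    (kinks only), so a tightly tolerated adaptive solver with a capped
    step handles them without event detection.  The cumulative net
    nitrogen flux is integrated as an auxiliary state so the
    conservation-law residual can be evaluated at solver accuracy.
    """
    if horizon <= 0.0:
        raise ValueError("horizon must be positive")
    if output_step <= 0.0 or output_step > horizon:
        raise ValueError("output_step must lie in (0, horizon]")

    n_steps = int(round(horizon / output_step))
    t_eval = np.linspace(0.0, horizon, n_steps + 1)

    y0 = np.append(initial.as_array(), 0.0)  # auxiliary: cumulative net N flux

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = _rhs(y[:5], params, strategy)
        return np.append(dy, _net_n_flux(y[:5], params, strategy))

    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        max_step=max_step,
    )
    if not sol.success:
        raise IntegrationError(
            f"solver failed for biome={params.biome!r} strategy={strategy.kind!r}: "
            f"{sol.message}"
        )

    pools = sol.y[:5]
    min_pool = pools.min()
    if min_pool < -NEGATIVE_POOL_TOLERANCE:
        raise IntegrationError(
            f"negative pool beyond tolerance ({min_pool:.3e}) for "
            f"biome={params.biome!r} strategy={strategy.kind!r}"
        )
    pools = np.clip(pools, 0.0, None)

    B_F, B_0, D, A, E = pools
    if strategy.kind == "none":
        F = np.zeros_like(A)
    else:
        B_tot = B_F + B_0
        demand = params.beta_F / (params.omega_F * (1.0 + params.gamma_F * B_tot)) \
            - params.nu_F * A
        F = np.clip(demand, strategy.F_min, strategy.F_max)

    return Trajectory(
        t=sol.t,
        B_F=B_F,
        B_0=B_0,
        D=D,
        A=A,
        E=E,
        F=F,
        fixation_flux=F * B_F,
        params=params,
        strategy=strategy,
        cumulative_n_flux=sol.y[5],
    )


def nitrogen_balance_residual(traj: Trajectory, params: ParameterSet | None = None) -> np.ndarray:
    """Nitrogen conservation residual along a trajectory (kg N/ha).

    Summing the pool equations weighted by N content gives the exact law

        d/dt [D + A + B_F/omega_F + B_0/omega_0]
            = I + F*B_F - (k + eta)*A - phi*D,

    so the stored total N minus the integrated net flux must stay at its
    initial value.  Uses the cumulative flux integrated with the solver
    when available, otherwise a trapezoidal quadrature of the flux on
    the output grid.
    """
    p = params if params is not None else traj.params
    n_total = traj.D + traj.A + traj.B_F / p.omega_F + traj.B_0 / p.omega_0
    if traj.cumulative_n_flux is not None:
        integral = traj.cumulative_n_flux
    else:
        flux = p.I + traj.fixation_flux - (p.k + p.eta) * traj.A - p.phi * traj.D
        integral = np.concatenate(
            ([0.0], np.cumsum(0.5 * (flux[1:] + flux[:-1]) * np.diff(traj.t)))
        )
    return n_total - (n_total[0] + integral)


def fixation_summary(traj: Trajectory) -> tuple[float, float, float]:
    """(time-mean, min, max) of the ecosystem fixation flux F*B_F
    (kg N/ha/yr), the mean taken by trapezoidal quadrature."""
    flux = traj.fixation_flux
    mean = float(np.trapezoid(flux, traj.t) / (traj.t[-1] - traj.t[0]))
    return mean, float(flux.min()), float(flux.max())


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

#: Biomass below this is treated as an extinct pool when refining equilibria.
_EXTINCTION_PIN = 1e-4


def steady_state(
    params: ParameterSet,
    strategy: FixationStrategy,
    initial_guess: EcosystemState | None = None,
    spinup: float = 3000.0,
    tol: float = 1e-7,
) -> SteadyState:
    """Locate a steady state by long-horizon integration plus root refinement.

    Integrates from ``initial_guess`` (default: a lightly seeded young
    stand) for ``spinup`` years, pins pools that have collapsed below an
    extinction threshold to zero, and polishes the remainder with a root
    solve of the right-hand side.  Reports the active Liebig branch of
    each species at the equilibrium.
    """
    if initial_guess is None:
        seed = 0.0 if strategy.kind == "none" else 10.0
        initial_guess = EcosystemState(B_F=seed, B_0=10.0, D=10.0, A=1.0, E=0.0)

    traj = simulate(
        initial_guess, params, strategy,
        horizon=spinup, output_step=spinup / 200.0, max_step=1.0,
    )
    y = traj.final.as_array()

    pinned = [i for i in (0, 1) if y[i] < _EXTINCTION_PIN]
    if strategy.kind == "none":
        pinned = sorted(set(pinned) | {0})
    free = [i for i in range(5) if i not in pinned]

    def reduced(x: np.ndarray) -> np.ndarray:
        full = np.zeros(5)
        full[free] = x
        return _rhs(full, params, strategy)[free]

    sol = root(reduced, y[free], method="hybr", tol=1e-12)
    if sol.success:
        y_ref = np.zeros(5)
        y_ref[free] = sol.x
        if y_ref.min() >= -NEGATIVE_POOL_TOLERANCE:
            y = np.clip(y_ref, 0.0, None)

    residual = float(np.max(np.abs(_rhs(y, params, strategy))))
    scale = float(np.max(np.abs(y)) + 1.0)
    if residual > tol * scale:
        raise IntegrationError(
            f"no steady state found (residual {residual:.3e} for scale {scale:.3e}); "
            "increase spinup or check parameters"
        )

    B_F, B_0, D, A, E = (float(v) for v in y)
    p = params
    if strategy.kind == "none" or B_F <= _EXTINCTION_PIN:
        fixer_branch = "absent"
        F = 0.0
    else:
        F = fixation_rate(A, B_F + B_0, p, strategy)
        n_lim = p.omega_F * (p.nu_F * A + F)
        dens = p.beta_F / (1.0 + p.gamma_F * (B_F + B_0))
        fixer_branch = "n_limited" if n_lim < dens else "density_limited"
    if B_0 <= _EXTINCTION_PIN:
        nonfixer_branch = "absent"
    else:
        n_lim = p.omega_0 * p.nu_0 * A
        dens = p.beta_0 / (1.0 + p.gamma_0 * (B_F + B_0))
        nonfixer_branch = "n_limited" if n_lim < dens else "density_limited"

    state = EcosystemState(B_F=B_F, B_0=B_0, D=D, A=A, E=E, t=float("inf"))
    return SteadyState(
        state=state,
        residual=residual,
        fixer_branch=fixer_branch,
        nonfixer_branch=nonfixer_branch,
        F=F,
    )
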