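"""The experimental design: scenario grids and the prescribed-fixation sweep.

A scenario is one cell of the factorial design — biome x community
composition x N-deposition level x initial-soil-N level — simulated for
100 years.  The grid runner produces absolute effects for every cell and
relative effects (composition minus the matching non-fixer-only cell)
under both accounting methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config as cfg
from .dynamics import EcosystemState, IntegrationError, Trajectory, simulate
from .effects import effects_for, relative_effect
from .params import FixationStrategy, ParameterSet

__all__ = [
    "Scenario",
    "load_parameterization",
    "run_scenario",
    "run_experiment_grid",
    "initial_soil_sensitivity",
    "single_pool_sweep",
]

logger = logging.getLogger(__name__)

KG_PER_MG = 1000.0


@dataclass(frozen=True)
class Scenario:
    """One cell of the experimental design."""

    biome: str
    composition: str
    deposition: str | float = "intermediate_2006"
    initial_n: str = "intermediate"

    def __post_init__(self) -> None:
        if self.composition not in cfg.COMPOSITIONS:
            raise ValueError(
                f"composition must be one of {cfg.COMPOSITIONS}, got {self.composition!r}"
            )
        if isinstance(self.deposition, (int, float)) and self.deposition < 0:
            raise ValueError("custom deposition must be >= 0")


def load_parameterization(biome: str, config: dict) -> ParameterSet:
    """Validated ParameterSet for a biome section of the configuration."""
    return cfg.get_parameter_set(config, biome)


def run_scenario(config: dict, scenario: Scenario) -> Trajectory:
    """Simulate one scenario cell over the configured horizon."""
    solver = cfg.get_solver_options(config)
    params = cfg.get_parameter_set(config, scenario.biome, scenario.deposition)
    strategy = cfg.get_strategy(config, scenario.biome, scenario.composition)
    initial = cfg.get_initial_state(
        config, scenario.biome, scenario.initial_n, scenario.composition
    )
    return simulate(
        initial,
        params,
        strategy,
        horizon=solver["horizon"],
        output_step=solver["output_step"],
        rtol=solver["rtol"],
        atol=solver["atol"],
        max_step=solver["max_step"],
    )


_EFFECT_COLUMNS = [
    "co2_gwp", "n2o_gwp", "net_gwp", "co2_rf", "n2o_rf", "net_rf",
]


def run_experiment_grid(
    config: dict,
    biomes: list[str] | None = None,
    deposition_levels: list[str] | None = None,
    initial_n_levels: list[str] | None = None,
    compositions: list[str] | None = None,
) -> pd.DataFrame:
    """Run the full factorial design and tabulate effects.

    Returns a tidy frame with one row per (biome, composition,
    deposition, initial_n, kind) where ``kind`` is "absolute" or
    "relative" (relative rows difference each fixer composition against
    the matched non-fixer-only cell).  Effects are reported under both
    methods in columns ``{co2,n2o,net}_{gwp,rf}``.  A failed integration
    aborts only its cell (logged), not the grid.
    """
    exp = config.get("experiment", {})
    biomes = biomes if biomes is not None else cfg.biome_names(config)
    deposition_levels = deposition_levels if deposition_levels is not None \
        else list(exp.get("deposition_levels", ["low", "intermediate_2006", "high_2030"]))
    initial_n_levels = initial_n_levels if initial_n_levels is not None \
        else list(exp.get("initial_n_levels", ["low", "intermediate", "high"]))
    compositions = compositions if compositions is not None \
        else list(exp.get("compositions", list(cfg.COMPOSITIONS)))
    consts = cfg.get_radiative_constants(config)

    rows: list[dict] = []
    for biome in biomes:
        for dep in deposition_levels:
            for init_n in initial_n_levels:
                cell_effects: dict[str, dict] = {}
                for comp in compositions:
                    scenario = Scenario(biome, comp, dep, init_n)
                    try:
                        traj = run_scenario(config, scenario)
                    except IntegrationError as err:
                        logger.warning("scenario %s failed: %s", scenario, err)
                        continue
                    gwp = effects_for(traj, "gwp", consts)
                    rf = effects_for(traj, "radiative_forcing", consts)
                    cell_effects[comp] = {"gwp": gwp, "rf": rf}
                    rows.append({
                        "biome": biome, "composition": comp, "deposition": dep,
                        "initial_n": init_n, "kind": "absolute",
                        "co2_gwp": gwp.co2_effect, "n2o_gwp": gwp.n2o_effect,
                        "net_gwp": gwp.net_effect,
                        "co2_rf": rf.co2_effect, "n2o_rf": rf.n2o_effect,
                        "net_rf": rf.net_effect,
                    })
                base = cell_effects.get("non_fixer")
                if base is None:
                    continue
                for comp, eff in cell_effects.items():
                    if comp == "non_fixer":
                        continue
                    rel_gwp = relative_effect(eff["gwp"], base["gwp"])
                    rel_rf = relative_effect(eff["rf"], base["rf"])
                    rows.append({
                        "biome": biome, "composition": comp, "deposition": dep,
                        "initial_n": init_n, "kind": "relative",
                        "co2_gwp": rel_gwp.co2_effect, "n2o_gwp": rel_gwp.n2o_effect,
                        "net_gwp": rel_gwp.net_effect,
                        "co2_rf": rel_rf.co2_effect, "n2o_rf": rel_rf.n2o_effect,
                        "net_rf": rel_rf.net_effect,
                    })
    return pd.DataFrame(rows)


def initial_soil_sensitivity(results: pd.DataFrame) -> pd.DataFrame:
    """Spread of net relative effects across initial-soil-N levels.

    For each (biome, composition, deposition), the max-minus-min of the
    net relative GWP effect over the initial-N levels, in
    Mg CO2-eq ha^-1 yr^-1.
    """
    rel = results[results["kind"] == "relative"]
    if rel.empty:
        return pd.DataFrame(
            columns=["biome", "composition", "deposition", "spread_mg_co2"]
        )
    grouped = (
        rel.groupby(["biome", "composition", "deposition"], sort=False)["net_gwp"]
        .agg(lambda s: (s.max() - s.min()) / KG_PER_MG)
        .reset_index(name="spread_mg_co2")
    )
    return grouped


def _single_pool_setup(
    F: float,
    params: ParameterSet,
    seed_biomass: float,
) -> tuple[EcosystemState, ParameterSet, FixationStrategy, str]:
    """Reduced model: one biomass pool with fixer physiology and a
    prescribed constant fixation rate.

    For F > 0 this is the full model with the non-fixer pool empty and
    an obligate strategy pinned at F.  For F = 0 the fixer constants are
    copied into the non-fixer slots and the fixer pool suppressed, which
    realizes the same single-pool dynamics without fixation.
    """
    if F < 0:
        raise ValueError("prescribed fixation rate must be >= 0")
    if F > 0:
        initial = EcosystemState(B_F=seed_biomass, B_0=0.0, D=0.0, A=0.0)
        return initial, params, FixationStrategy.obligate(F), "B_F"
    swapped = params.replace(
        omega_0=params.omega_F, nu_0=params.nu_F, beta_0=params.beta_F,
        gamma_0=params.gamma_F, mu_0=params.mu_F,
    )
    initial = EcosystemState(B_F=0.0, B_0=seed_biomass, D=0.0, A=0.0)
    return initial, swapped, FixationStrategy.none(), "B_0"


def single_pool_sweep(
    F_values,
    params: ParameterSet,
    deposition: float,
    config: dict | None = None,
    seed_biomass: float = 10.0,
) -> pd.DataFrame:
    """CO2 and N2O effects of a single-pool stand as a function of a
    prescribed, constant N fixation rate per unit biomass C.

    The initial soil pools are empty so the sweep isolates the effect of
    fixation against deposition.  Returns one row per F with both
    methods' effects and the realized mean ecosystem fixation flux.
    """
    from .dynamics import fixation_summary  # local import to avoid cycle noise

    config = config or cfg.default_config()
    solver = cfg.get_solver_options(config)
    consts = cfg.get_radiative_constants(config)
    base = params.with_deposition(deposition)

    rows = []
    for F in np.atleast_1d(np.asarray(F_values, dtype=float)):
        initial, p, strategy, _pool = _single_pool_setup(float(F), base, seed_biomass)
        traj = simulate(
            initial, p, strategy,
            horizon=solver["horizon"], output_step=solver["output_step"],
            rtol=solver["rtol"], atol=solver["atol"], max_step=solver["max_step"],
        )
        gwp = effects_for(traj, "gwp", consts)
        rf = effects_for(traj, "radiative_forcing", consts)
        mean_flux, _, max_flux = fixation_summary(traj)
        rows.append({
            "F": float(F),
            "co2_gwp": gwp.co2_effect, "n2o_gwp": gwp.n2o_effect,
            "net_gwp": gwp.net_effect,
            "co2_rf": rf.co2_effect, "n2o_rf": rf.n2o_effect,
            "net_rf": rf.net_effect,
            "mean_fixation_flux": mean_flux, "max_fixation_flux": max_flux,
        })
    return pd.DataFrame(rows)
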