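"""Biome-to-globe upscaling of per-hectare effects.

Per-hectare net CO2-N2O effects computed with the tropical, temperate
and boreal parameterizations are applied to the corresponding forest
areas and summed into global totals expressed in Pg C yr^-1 of carbon
radiative equivalents (negative = cooling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import config as cfg
from .effects import effects_for, relative_effect, to_c_equivalents
from .scenarios import Scenario, run_scenario

__all__ = [
    "GlobalEstimate",
    "area_weighted_deposition",
    "global_net_effect",
    "per_biome_net_effects",
    "global_composition_table",
    "mixture_surface",
    "sink_offset_percent",
]

KG_PER_PG = 1e12


@dataclass(frozen=True)
class GlobalEstimate:
    """An area-weighted global effect for one community composition."""

    composition: str
    areas_ha: dict
    per_ha_effects: dict           # kg CO2-eq ha^-1 yr^-1 (net, GWP method)
    global_effect_pg_c: float      # Pg C yr^-1, C radiative equivalents
    relative_effect_pg_c: float | None = None  # vs non-fixer composition


def area_weighted_deposition(values: Sequence[float], areas: Sequence[float]) -> float:
    """Area-weighted mean of per-region values (used to collapse global
    deposition fields onto biome scalars)."""
    values = np.asarray(values, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if values.shape != areas.shape:
        raise ValueError(f"shape mismatch: values {values.shape} vs areas {areas.shape}")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    return float(np.sum(values * areas) / np.sum(areas))


def _to_pg_c(per_ha_effects: Mapping[str, float], areas: Mapping[str, float]) -> float:
    missing = sorted(set(areas) - set(per_ha_effects))
    if missing:
        raise KeyError(f"missing per-biome effect(s) for: {', '.join(missing)}")
    total_co2eq = sum(areas[b] * per_ha_effects[b] for b in areas)  # kg CO2-eq/yr
    return to_c_equivalents(total_co2eq) / KG_PER_PG


def global_net_effect(
    per_biome_effects: Mapping[str, float],
    areas: Mapping[str, float],
    composition: str,
    nonfixer_effects: Mapping[str, float] | None = None,
) -> GlobalEstimate:
    """Combine per-hectare net effects (kg CO2-eq ha^-1 yr^-1) with forest
    areas into a global Pg C yr^-1 radiative-equivalent estimate.

    When the matching non-fixer per-biome effects are supplied, the
    relative effect (composition minus non-fixer) is reported as well.
    """
    for biome, area in areas.items():
        if area <= 0:
            raise ValueError(f"area for {biome!r} must be positive")
    value = _to_pg_c(per_biome_effects, areas)
    relative = None
    if nonfixer_effects is not None:
        relative = value - _to_pg_c(nonfixer_effects, areas)
    return GlobalEstimate(
        composition=composition,
        areas_ha=dict(areas),
        per_ha_effects=dict(per_biome_effects),
        global_effect_pg_c=value,
        relative_effect_pg_c=relative,
    )


def per_biome_net_effects(
    config: dict,
    composition: str,
    deposition: str | Mapping[str, float] = "high_2030",
    initial_n: str = "intermediate",
    method: str = "gwp",
) -> dict[str, float]:
    """Net effect per hectare (kg CO2-eq ha^-1 yr^-1) for each biome.

    ``deposition`` is either a scenario label resolved per biome, or an
    explicit mapping biome -> kg N/ha/yr.
    """
    consts = cfg.get_radiative_constants(config)
    out = {}
    for biome in cfg.biome_names(config):
        dep = deposition[biome] if isinstance(deposition, Mapping) else deposition
        traj = run_scenario(config, Scenario(biome, composition, dep, initial_n))
        out[biome] = effects_for(traj, method, consts).net_effect
    return out


def global_composition_table(
    config: dict,
    deposition: str = "high_2030",
    compositions: Sequence[str] = ("non_fixer", "obligate", "facultative", "incomplete_regulator"),
    initial_n: str = "intermediate",
) -> pd.DataFrame:
    """Global net CO2-N2O effect of forests and of N-fixing trees
    relative to non-fixing trees, per composition scenario (the global
    summary table of the analysis)."""
    areas = {b: float(a) for b, a in config["global"]["areas_ha"].items()}
    effects = {
        comp: per_biome_net_effects(config, comp, deposition, initial_n)
        for comp in compositions
    }
    if "non_fixer" not in effects:
        raise ValueError("compositions must include 'non_fixer' as the baseline")
    base = effects["non_fixer"]
    rows = []
    for comp in compositions:
        est = global_net_effect(
            effects[comp], areas, comp,
            nonfixer_effects=None if comp == "non_fixer" else base,
        )
        rows.append({
            "composition": comp,
            "global_net_effect_pg_c": est.global_effect_pg_c,
            "relative_effect_pg_c": est.relative_effect_pg_c,
        })
    return pd.DataFrame(rows)


def _relative_global_effect_at(
    config: dict,
    composition: str,
    deposition_by_biome: Mapping[str, float],
    areas: Mapping[str, float],
    initial_n: str = "intermediate",
) -> float:
    eff = per_biome_net_effects(config, composition, deposition_by_biome, initial_n)
    base = per_biome_net_effects(config, "non_fixer", deposition_by_biome, initial_n)
    return _to_pg_c(eff, areas) - _to_pg_c(base, areas)


def mixture_surface(
    config: dict,
    p_grid: Sequence[float],
    deposition_fractions: Sequence[float],
    initial_n: str = "intermediate",
) -> pd.DataFrame:
    """Global relative effect for mixtures of obligate- and
    facultative-fixer ecosystems across a deposition gradient.

    ``p_grid`` is the fraction of forest area occupied by ecosystems
    with obligate fixers (the rest facultative).  Each deposition
    fraction s in [0, 1] interpolates every biome's rate linearly
    between its minimum recent level (min of the 2001/2006 entries) and
    its projected 2030 level.  The surface value is the linear mixture
    p * obligate-endpoint + (1 - p) * facultative-endpoint, so the
    endpoint rows reproduce the pure-scenario curves exactly.
    """
    p_grid = np.asarray(p_grid, dtype=float)
    if np.any((p_grid < 0) | (p_grid > 1)):
        raise ValueError("mixture fractions p must lie in [0, 1]")
    s_grid = np.asarray(deposition_fractions, dtype=float)
    if np.any((s_grid < 0) | (s_grid > 1)):
        raise ValueError("deposition fractions must lie in [0, 1]")

    areas = {b: float(a) for b, a in config["global"]["areas_ha"].items()}
    rows = []
    for s in s_grid:
        dep = {}
        for biome in cfg.biome_names(config):
            levels = config["biomes"][biome]["deposition"]
            recent = min(float(levels["intermediate_2001"]), float(levels["intermediate_2006"]))
            future = float(levels["high_2030"])
            dep[biome] = recent + s * (future - recent)
        rel_ob = _relative_global_effect_at(config, "obligate", dep, areas, initial_n)
        rel_fac = _relative_global_effect_at(config, "facultative", dep, areas, initial_n)
        for p in p_grid:
            rows.append({
                "p_obligate": float(p),
                "deposition_fraction": float(s),
                "relative_effect_pg_c": p * rel_ob + (1.0 - p) * rel_fac,
                "obligate_endpoint_pg_c": rel_ob,
                "facultative_endpoint_pg_c": rel_fac,
            })
    return pd.DataFrame(rows)


def sink_offset_percent(relative_effect_pg_c: float, global_sink_pg_c: float = 2.4) -> float:
    """The relative effect of N-fixing trees as a percentage of the
    current global forest carbon sink (positive = the sink's negative
    forcing is reduced by that fraction)."""
    if global_sink_pg_c <= 0:
        raise ValueError("global sink must be positive")
    return 100.0 * relative_effect_pg_c / global_sink_pg_c
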