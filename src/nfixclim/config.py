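"""Configuration loading and typed accessors.

The study configuration is a nested mapping (shipped as a YAML default
inside the package) holding per-biome parameter sets, fixation-strategy
constants, nitrogen-deposition scenarios, initial pools, calibration
anchors, radiative constants, solver settings and global forest areas.
A user file overrides the defaults key-by-key (deep merge).
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .dynamics import EcosystemState
from .params import FixationStrategy, ParameterSet, RadiativeConstants

__all__ = [
    "default_config",
    "load_config",
    "biome_names",
    "get_parameter_set",
    "get_strategy",
    "get_initial_state",
    "get_radiative_constants",
    "get_solver_options",
    "deposition_rate",
]

COMPOSITIONS = ("non_fixer", "obligate", "facultative", "incomplete_regulator")

#: Map experiment composition labels to strategy kinds.
COMPOSITION_TO_KIND = {
    "non_fixer": "none",
    "obligate": "obligate",
    "facultative": "facultative",
    "incomplete_regulator": "incomplete_regulator",
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def default_config() -> dict:
    """The packaged default study configuration."""
    text = resources.files("nfixclim").joinpath("data/default_config.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict:
    """Load a configuration file, deep-merged over the packaged defaults."""
    config = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        config = _deep_merge(config, user)
    return config


def biome_names(config: Mapping) -> list[str]:
    return list(config["biomes"])


def _biome_section(config: Mapping, biome: str) -> Mapping:
    try:
        return config["biomes"][biome]
    except KeyError:
        known = ", ".join(config.get("biomes", {}))
        raise KeyError(f"biome {biome!r} not in config (have: {known})") from None


def deposition_rate(config: Mapping, biome: str, level: str | float) -> float:
    """Resolve a deposition level label (or a custom numeric rate) to
    kg N/ha/yr."""
    if isinstance(level, (int, float)):
        if level < 0:
            raise ValueError("custom deposition rate must be >= 0")
        return float(level)
    section = _biome_section(config, biome)["deposition"]
    try:
        return float(section[level])
    except KeyError:
        known = ", ".join(section)
        raise KeyError(
            f"deposition level {level!r} not in config for biome {biome!r} "
            f"(have: {known})"
        ) from None


def get_parameter_set(
    config: Mapping,
    biome: str,
    deposition: str | float | None = None,
) -> ParameterSet:
    """Build the validated ParameterSet for a biome.

    ``deposition`` may be a scenario label (e.g. "high_2030") or a custom
    numeric rate; when omitted, the biome's configured ``I`` is kept.
    """
    section = _biome_section(config, biome)
    params = ParameterSet.from_dict(section["parameters"], biome=biome)
    if deposition is not None:
        params = params.with_deposition(deposition_rate(config, biome, deposition))
    return params


def get_strategy(config: Mapping, biome: str, composition: str) -> FixationStrategy:
    """The FixationStrategy for a composition label in a biome."""
    if composition not in COMPOSITION_TO_KIND:
        raise KeyError(
            f"unknown composition {composition!r} (have: {', '.join(COMPOSITION_TO_KIND)})"
        )
    kind = COMPOSITION_TO_KIND[composition]
    section = _biome_section(config, biome)["strategy"]
    F_max = float(section["F_max"])
    F_min = F_max * float(section.get("F_min_fraction", 0.5))
    return FixationStrategy.from_kind(kind, F_max, F_min)


def get_initial_state(
    config: Mapping,
    biome: str,
    initial_n: str = "intermediate",
    composition: str = "obligate",
) -> EcosystemState:
    """Initial pools for a scenario: small equal biomass seeding (fixer
    seed zeroed for non-fixer-only runs), configured initial soil N, and
    no accumulated atmospheric N2O."""
    section = _biome_section(config, biome)
    soil = section["initial_soil_n"][initial_n]
    biomass = section.get("initial_biomass", {"B_F": 10.0, "B_0": 10.0})
    B_F = 0.0 if composition == "non_fixer" else float(biomass["B_F"])
    return EcosystemState(
        B_F=B_F,
        B_0=float(biomass["B_0"]),
        D=float(soil["D"]),
        A=float(soil["A"]),
        E=0.0,
    )


def get_radiative_constants(config: Mapping) -> RadiativeConstants:
    overrides = config.get("radiative_constants", {})
    return RadiativeConstants(**{k: float(v) for k, v in overrides.items()})


def get_solver_options(config: Mapping) -> dict:
    solver = config.get("solver", {})
    out = {
        "rtol": float(solver.get("rtol", 1e-8)),
        "atol": float(solver.get("atol", 1e-10)),
        "max_step": float(solver.get("max_step", 0.1)),
        "output_step": float(solver.get("output_step", 0.1)),
        "horizon": float(solver.get("horizon", 100.0)),
    }
    for key, value in out.items():
        if value <= 0:
            raise ValueError(f"solver option {key!r} must be positive, got {value!r}")
    return out
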