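"""Parameter containers for the coupled carbon-nitrogen ecosystem model.

The model tracks two tree biomass carbon pools (nitrogen fixers and
non-fixers), two soil nitrogen pools (plant-unavailable detrital N and
plant-available N), and the atmospheric N2O burden attributable to the
simulated hectare.  All rate parameters are per year; stocks are per
hectare.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Mapping

__all__ = [
    "ParameterSet",
    "FixationStrategy",
    "RadiativeConstants",
    "STRATEGY_KINDS",
]

#: Recognised nitrogen-fixation strategies, ordered from no fixation to
#: unregulated fixation.
STRATEGY_KINDS = ("none", "facultative", "incomplete_regulator", "obligate")


@dataclass(frozen=True)
class ParameterSet:
    """All rate and efficiency constants of the ecosystem model for one biome.

    Attributes
    ----------
    omega_F, omega_0:
        Nitrogen use efficiency of fixers / non-fixers (kg C per kg N);
        the inverse of tissue N:C.
    nu_F, nu_0:
        Plant-available N uptake coefficient (ha per kg C per yr).
    beta_F, beta_0:
        Maximum (non-N-limited) per-capita growth rate (1/yr).
    gamma_F, gamma_0:
        Density-dependence coefficient of non-N-limited growth
        (ha per kg C); stands in for light/phosphorus/space limitation.
    mu_F, mu_0:
        Biomass turnover rate (1/yr).
    m:
        Mineralization rate of plant-unavailable soil N (1/yr).
    phi:
        Loss rate of plant-unavailable soil N (1/yr).
    I:
        Abiotic N input, i.e. atmospheric N deposition (kg N/ha/yr).
    k:
        Loss rate of plant-available soil N other than N2O (leaching,
        NO, NH3, N2; 1/yr).
    eta:
        Gaseous loss rate of plant-available soil N as N2O (1/yr).
    psi:
        Atmospheric N2O removal rate (1/yr), the inverse of the
        atmospheric lifetime of N2O.
    biome:
        Free-form label ("tropical", "temperate", "boreal", ...).
    """

    omega_F: float
    omega_0: float
    nu_F: float
    nu_0: float
    beta_F: float
    beta_0: float
    gamma_F: float
    gamma_0: float
    mu_F: float
    mu_0: float
    m: float
    phi: float
    I: float
    k: float
    eta: float
    psi: float
    biome: str = "unlabeled"

    _POSITIVE = (
        "omega_F", "omega_0", "nu_F", "nu_0", "beta_F", "beta_0",
        "gamma_F", "gamma_0", "mu_F", "mu_0", "m", "phi", "k", "eta",
        "psi",
    )

    def __post_init__(self) -> None:
        for name in self._POSITIVE:
            value = getattr(self, name)
            if not value > 0.0:
                raise ValueError(f"parameter {name!r} must be > 0, got {value!r}")
        if self.I < 0.0:
            raise ValueError(f"deposition I must be >= 0, got {self.I!r}")

    # -- convenience -------------------------------------------------------
    def with_deposition(self, deposition: float) -> "ParameterSet":
        """Return a copy with the N deposition rate replaced."""
        return replace(self, I=float(deposition))

    def replace(self, **changes) -> "ParameterSet":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float], biome: str | None = None) -> "ParameterSet":
        """Build a ParameterSet from a mapping, reporting all missing keys."""
        required = [f.name for f in fields(cls) if f.name != "biome"]
        missing = [name for name in required if name not in mapping]
        if missing:
            raise KeyError(
                "missing parameter value(s): " + ", ".join(sorted(missing))
            )
        kwargs = {name: float(mapping[name]) for name in required}
        kwargs["biome"] = biome if biome is not None else str(mapping.get("biome", "unlabeled"))
        return cls(**kwargs)


@dataclass(frozen=True)
class FixationStrategy:
    """The (F_min, F_max) pair encoding a symbiotic N fixation strategy.

    ``F`` is the N fixation rate per unit biomass carbon
    (kg N per kg C per yr).  The realized rate is clamped to
    ``[F_min, F_max]`` around the fixer's unmet N demand:

    * obligate — ``F_min == F_max > 0`` (fixation never down-regulated),
    * facultative — ``F_min == 0 < F_max`` (fixation can shut off
      entirely once soil N meets demand),
    * incomplete_regulator — ``0 < F_min < F_max`` (down-regulates but
      sustains a minimum rate),
    * none — ``F_max == 0`` (the fixer pool is suppressed).
    """

    kind: str
    F_min: float
    F_max: float

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if not 0.0 <= self.F_min <= self.F_max:
            raise ValueError(
                f"need 0 <= F_min <= F_max, got ({self.F_min!r}, {self.F_max!r})"
            )
        kind = self.kind
        if kind == "none" and self.F_max != 0.0:
            raise ValueError("strategy 'none' requires F_max == 0")
        if kind == "obligate" and not (self.F_min == self.F_max > 0.0):
            raise ValueError("obligate strategy requires F_min == F_max > 0")
        if kind == "facultative" and not (self.F_min == 0.0 < self.F_max):
            raise ValueError("facultative strategy requires F_min == 0 < F_max")
        if kind == "incomplete_regulator" and not (0.0 < self.F_min < self.F_max):
            raise ValueError(
                "incomplete_regulator strategy requires 0 < F_min < F_max"
            )

    # -- constructors ------------------------------------------------------
    @classmethod
    def none(cls) -> "FixationStrategy":
        return cls("none", 0.0, 0.0)

    @classmethod
    def obligate(cls, F: float) -> "FixationStrategy":
        return cls("obligate", F, F)

    @classmethod
    def facultative(cls, F_max: float) -> "FixationStrategy":
        return cls("facultative", 0.0, F_max)

    @classmethod
    def incomplete_regulator(cls, F_min: float, F_max: float) -> "FixationStrategy":
        return cls("incomplete_regulator", F_min, F_max)

    @classmethod
    def from_kind(cls, kind: str, F_max: float, F_min: float | None = None) -> "FixationStrategy":
        """Build a strategy of the given kind from a shared ``F_max``.

        ``F_min`` is only consulted for the incomplete regulator.
        """
        if kind == "none":
            return cls.none()
        if kind == "obligate":
            return cls.obligate(F_max)
        if kind == "facultative":
            return cls.facultative(F_max)
        if kind == "incomplete_regulator":
            if F_min is None:
                raise ValueError("incomplete_regulator requires F_min")
            return cls.incomplete_regulator(F_min, F_max)
        raise ValueError(f"unknown strategy kind {kind!r}")


# Defaults: N2O GWP-100 of 298 (the AR4 value, still the common accounting
# convention); radiative efficiencies and the CO2 impulse-response fit from
# IPCC AR5 (Myhre et al. 2013, ch. 8) and Joos et al. (2013).
@dataclass(frozen=True)
class RadiativeConstants:
    """Constants of the two greenhouse-gas accounting methods.

    ``gwp_n2o`` drives the 100-yr global-warming-potential method; the
    remaining fields drive the continuous radiative-forcing method
    (CO2 impulse-response fractions/lifetimes and per-kilogram radiative
    efficiencies).
    """

    gwp_n2o: float = 298.0            # kg CO2 per kg N2O, 100-yr horizon
    re_co2_ppbv: float = 1.37e-5      # W m-2 ppbv-1
    re_n2o_ppbv: float = 3.03e-3      # W m-2 ppbv-1
    a_0: float = 0.2173               # impulse-response fractions (dimensionless)
    a_1: float = 0.2240
    a_2: float = 0.2824
    a_3: float = 0.2763
    tau_1: float = 394.4              # CO2 removal lifetimes, yr
    tau_2: float = 36.54
    tau_3: float = 4.304
    M_A: float = 28.97                # mean molar mass of air, g/mol
    M_CO2: float = 44.01              # g/mol
    M_N2O: float = 44.013             # g/mol
    T_M: float = 5.135e18             # total mass of the atmosphere, kg

    def __post_init__(self) -> None:
        total = self.a_0 + self.a_1 + self.a_2 + self.a_3
        if abs(total - 1.0) > 1e-3:
            raise ValueError(
                f"impulse-response fractions must sum to 1 (got {total!r})"
            )
        for name in ("gwp_n2o", "re_co2_ppbv", "re_n2o_ppbv",
                     "tau_1", "tau_2", "tau_3", "M_A", "M_CO2", "M_N2O", "T_M"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"constant {name!r} must be positive")

    @property
    def a(self) -> tuple[float, ...]:
        return (self.a_0, self.a_1, self.a_2, self.a_3)

    @property
    def tau(self) -> tuple[float, ...]:
        return (self.tau_1, self.tau_2, self.tau_3)

    def replace(self, **changes) -> "RadiativeConstants":
        return replace(self, **changes)


def iter_rate_names() -> Iterator[str]:
    """Names of the strictly positive rate/efficiency parameters."""
    yield from ParameterSet._POSITIVE
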