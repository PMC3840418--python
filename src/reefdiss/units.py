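"""Unit-checked conversions between areal CaCO3 mass fluxes and vertical framework rates.

Reef carbonate budgets are naturally expressed as an areal mass flux
(g CaCO3 cm^-2 d^-1 at the scale of a single incubation, kg CaCO3 m^-2 y^-1 at
the scale of a reef), while reef-growth models work in vertical framework
change (mm y^-1).  The two are linked by the mineral density of the skeleton
and the porosity of the consolidated framework:

    v [mm y^-1] = F [kg m^-2 y^-1] / (rho [kg m^-3] * (1 - phi)) * 1000

Sign convention: dissolution is a negative flux and a negative vertical rate;
magnitudes convert identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ArealMassRate",
    "FrameworkProperties",
    "UnitError",
    "convert_areal_mass_rate",
    "mass_rate_to_vertical_rate",
    "vertical_rate_to_mass_rate",
    "parse_unit_triple",
    "DAYS_PER_YEAR",
    "ARAGONITE_DENSITY_G_CM3",
    "DEFAULT_FRAMEWORK_POROSITY",
]

#: Year length used throughout (no leap handling).
DAYS_PER_YEAR = 365.0
#: Bulk crystal density of aragonite, the CaCO3 polymorph corals secrete.
ARAGONITE_DENSITY_G_CM3 = 2.9
#: Void fraction of consolidated reef framework (field-average assumption).
DEFAULT_FRAMEWORK_POROSITY = 0.5

# scale factors to canonical g / cm^2 / d
_MASS_G = {"g": 1.0, "kg": 1000.0}
_AREA_CM2 = {"cm2": 1.0, "m2": 1.0e4}
_TIME_D = {"d": 1.0, "y": DAYS_PER_YEAR}

_MASS_ALIASES = {"g": "g", "kg": "kg"}
_AREA_ALIASES = {"cm2": "cm2", "cm^2": "cm2", "cm²": "cm2", "m2": "m2", "m^2": "m2", "m²": "m2"}
_TIME_ALIASES = {"d": "d", "day": "d", "y": "y", "yr": "y", "year": "y"}


class UnitError(ValueError):
    """Raised for unknown unit tokens or invalid framework properties."""


def _norm(token: str, aliases: dict[str, str], kind: str) -> str:
    try:
        return aliases[token.strip().lower()]
    except KeyError:
        raise UnitError(f"unknown {kind} unit {token!r}") from None


def parse_unit_triple(spec: str) -> tuple[str, str, str]:
    """Parse a ``"mass/area/time"`` string (e.g. ``"kg/m2/y"``) into a unit triple."""
    parts = spec.split("/")
    if len(parts) != 3:
        raise UnitError(f"expected 'mass/area/time', got {spec!r}")
    return (
        _norm(parts[0], _MASS_ALIASES, "mass"),
        _norm(parts[1], _AREA_ALIASES, "area"),
        _norm(parts[2], _TIME_ALIASES, "time"),
    )


@dataclass(frozen=True)
class ArealMassRate:
    """A CaCO3 mass flux per unit area per unit time with explicit units.

    Parameters
    ----------
    value : float
        Flux magnitude; negative for dissolution.
    mass_unit, area_unit, time_unit : str
        One of {g, kg}, {cm2, m2}, {d, y}.
    """

    value: float
    mass_unit: str = "g"
    area_unit: str = "cm2"
    time_unit: str = "d"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mass_unit", _norm(self.mass_unit, _MASS_ALIASES, "mass"))
        object.__setattr__(self, "area_unit", _norm(self.area_unit, _AREA_ALIASES, "area"))
        object.__setattr__(self, "time_unit", _norm(self.time_unit, _TIME_ALIASES, "time"))
        if not math.isfinite(self.value):
            raise UnitError(f"flux value must be finite, got {self.value!r}")

    @property
    def units(self) -> str:
        return f"{self.mass_unit}/{self.area_unit}/{self.time_unit}"

    def to(self, target_units: str | tuple[str, str, str]) -> "ArealMassRate":
        return convert_areal_mass_rate(self, target_units)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ArealMassRate({self.value:g} {self.units})"


@dataclass(frozen=True)
class FrameworkProperties:
    """Mineral density and framework porosity used for mass <-> thickness conversion.

    ``mineral_density`` is in g cm^-3 (> 0); ``framework_porosity`` is the void
    fraction of the consolidated framework, in [0, 1).
    """

    mineral_density: float = ARAGONITE_DENSITY_G_CM3
    framework_porosity: float = DEFAULT_FRAMEWORK_POROSITY

    def __post_init__(self) -> None:
        if not (self.mineral_density > 0 and math.isfinite(self.mineral_density)):
            raise UnitError(f"mineral_density must be > 0, got {self.mineral_density!r}")
        if not (0.0 <= self.framework_porosity < 1.0):
            raise UnitError(
                f"framework_porosity must lie in [0, 1), got {self.framework_porosity!r}"
            )


def convert_areal_mass_rate(
    rate: ArealMassRate, target_units: str | tuple[str, str, str]
) -> ArealMassRate:
    """Convert ``rate`` to ``target_units``, an exact bijection between unit triples.

    >>> convert_areal_mass_rate(ArealMassRate(4.2e-5, "g", "cm2", "d"), "g/m2/d").value
    0.42000000000000004
    """
    if isinstance(target_units, str):
        m, a, t = parse_unit_triple(target_units)
    else:
        m, a, t = target_units
        m = _norm(m, _MASS_ALIASES, "mass")
        a = _norm(a, _AREA_ALIASES, "area")
        t = _norm(t, _TIME_ALIASES, "time")
    canonical = rate.value * _MASS_G[rate.mass_unit] / _AREA_CM2[rate.area_unit] / _TIME_D[rate.time_unit]
    value = canonical / _MASS_G[m] * _AREA_CM2[a] * _TIME_D[t]
    return ArealMassRate(value, m, a, t)


def mass_rate_to_vertical_rate(
    rate: ArealMassRate | float, props: FrameworkProperties | None = None
) -> float:
    """Convert an areal CaCO3 flux to a vertical framework rate in mm y^-1.

    A bare float is interpreted as kg m^-2 y^-1.  The flux is divided by the
    solid-mineral density scaled by the framework solid fraction (1 - porosity):
    a more porous framework gains (or loses) more thickness per unit mass.
    """
    props = props or FrameworkProperties()
    if not isinstance(rate, ArealMassRate):
        rate = ArealMassRate(float(rate), "kg", "m2", "y")
    f = convert_areal_mass_rate(rate, ("kg", "m2", "y")).value
    rho_kg_m3 = props.mineral_density * 1000.0
    return f / (rho_kg_m3 * (1.0 - props.framework_porosity)) * 1000.0


def vertical_rate_to_mass_rate(
    v_mm_per_y: float, props: FrameworkProperties | None = None
) -> ArealMassRate:
    """Exact inverse of :func:`mass_rate_to_vertical_rate`; returns kg m^-2 y^-1."""
    props = props or FrameworkProperties()
    rho_kg_m3 = props.mineral_density * 1000.0
    f = v_mm_per_y / 1000.0 * rho_kg_m3 * (1.0 - props.framework_porosity)
    return ArealMassRate(f, "kg", "m2", "y")
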