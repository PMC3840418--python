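"""Sea-level trajectories for the B1 / A2 / A1FI emission scenarios, 1990–2100.

Two generation modes are provided:

* **semi-empirical** — the rise rate is a linear function of the global
  temperature anomaly and its rate of change,
  ``dH/dt = a_sl * (T - T0) + b_sl * dT/dt`` (mm y^-1), integrated with the
  same fixed-step RK4 scheme used by the reef model.  Default constants
  (a_sl = 5.6 mm y^-1 K^-1, b_sl = -49 mm K^-1, T0 = -0.41 degC) follow the
  published dual-term semi-empirical calibration and are fully configurable.
* **parametric** — an accelerating power law anchored at a known 2100
  endpoint, ``H(t) = rise_2100 * ((t - t0)/(t1 - t0))**p``, for when only the
  end-of-century rise (e.g. 75–90 cm) is specified.

Scenario warming endpoints: B1 +1.8 degC, A2 +3.4 degC, A1FI +4.0 degC above
the 1990 baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._integrate import rk4_path
from .trajectory import Trajectory

__all__ = [
    "EmissionScenario",
    "SCENARIOS",
    "SemiEmpiricalParams",
    "temperature_trajectory",
    "semi_empirical_rate",
    "integrate_sea_level",
    "parametric_sea_level",
    "scenario_sea_level",
    "average_rate",
]


@dataclass(frozen=True)
class EmissionScenario:
    """An emission scenario: warming by 2100 and (optionally) a nominal 2100 rise."""

    name: str
    delta_T_2100: float  # degC above the 1990 baseline
    nominal_rise_2100: float | None = None  # mm, for the parametric mode

    def __post_init__(self) -> None:
        if not self.delta_T_2100 > 0:
            raise ValueError("delta_T_2100 must be > 0")


def _canonical_name(name: str) -> str:
    # the source literature occasionally prints "A1F1" for the fossil-intensive scenario
    n = name.strip().upper()
    return "A1FI" if n == "A1F1" else n


#: Default scenario set: warming endpoints with parametric 2100 rises spanning 75–90 cm.
SCENARIOS: dict[str, EmissionScenario] = {
    "B1": EmissionScenario("B1", 1.8, 750.0),
    "A2": EmissionScenario("A2", 3.4, 850.0),
    "A1FI": EmissionScenario("A1FI", 4.0, 900.0),
}


def get_scenario(name: str) -> EmissionScenario:
    key = _canonical_name(name)
    if key not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    return SCENARIOS[key]


@dataclass(frozen=True)
class SemiEmpiricalParams:
    """Constants of the dual-term semi-empirical sea-level model.

    ``a_sl`` (mm y^-1 K^-1) scales the rise rate with the temperature anomaly
    relative to ``T0`` (degC); ``b_sl`` (mm K^-1) is the fast-response term
    multiplying dT/dt.
    """

    a_sl: float = 5.6
    b_sl: float = -49.0
    T0: float = -0.41

    def __post_init__(self) -> None:
        if not np.isfinite(self.a_sl):
            raise ValueError("a_sl must be finite")


def _year_grid(t0: float, t1: float, step: float) -> np.ndarray:
    """Uniform grid from t0 toward t1 built by index (no float accumulation)."""
    n = int(np.floor((t1 - t0) / step + 1e-9))
    years = t0 + step * np.arange(n + 1)
    years[-1] = min(years[-1], t1)
    return years


def temperature_trajectory(
    scenario: EmissionScenario | str,
    t0: float = 1990.0,
    t1: float = 2100.0,
    step: float = 1.0,
    shape: str = "linear",
) -> Trajectory:
    """Temperature-anomaly ramp from 0 at ``t0`` to the scenario's warming at ``t1``.

    ``shape='linear'`` is a straight ramp; ``shape='smooth'`` is the monotone
    cubic ``dT * (3 s^2 - 2 s^3)`` with zero initial slope.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    if not t0 < t1:
        raise ValueError("need t0 < t1")
    if not step > 0:
        raise ValueError("step must be > 0")
    years = _year_grid(t0, t1, step)
    s = (years - t0) / (t1 - t0)
    if shape == "linear":
        values = scenario.delta_T_2100 * s
    elif shape == "smooth":
        values = scenario.delta_T_2100 * (3 * s**2 - 2 * s**3)
    else:
        raise ValueError(f"unknown shape {shape!r}; use 'linear' or 'smooth'")
    return Trajectory(years, values, "temperature_degC", {"scenario": scenario.name, "shape": shape})


def semi_empirical_rate(T: float, dTdt: float, params: SemiEmpiricalParams) -> float:
    """Instantaneous sea-level rise rate ``a_sl * (T - T0) + b_sl * dT/dt`` in mm y^-1."""
    return params.a_sl * (T - params.T0) + params.b_sl * dTdt


def integrate_sea_level(
    temp: Trajectory,
    params: SemiEmpiricalParams | None = None,
    step: float = 0.1,
) -> Trajectory:
    """Integrate the semi-empirical rate over a temperature trajectory; H(t0) = 0.

    Fixed-step classical RK4 on the interpolated anomaly and its (centered
    finite-difference) time derivative, reported on the temperature grid.
    """
    params = params or SemiEmpiricalParams()
    if len(temp) < 2:
        raise ValueError("temperature trajectory needs at least 2 points")
    dTdt_grid = temp.rate()

    def rhs(t: float, _H: float) -> float:
        T = np.interp(t, temp.years, temp.values)
        dTdt = np.interp(t, temp.years, dTdt_grid)
        return semi_empirical_rate(float(T), float(dTdt), params)

    values = rk4_path(rhs, 0.0, temp.years, step)
    return Trajectory(
        temp.years,
        values,
        "sea_level_mm",
        {"mode": "semi_empirical", **temp.metadata},
    )


def parametric_sea_level(
    rise_2100: float,
    exponent: float = 2.0,
    t0: float = 1990.0,
    t1: float = 2100.0,
    step: float = 1.0,
    name: str = "",
) -> Trajectory:
    """Power-law rise anchored at the endpoint: ``H(t) = rise_2100 * s**p``, s in [0, 1].

    ``exponent >= 1`` (accelerating or linear); the curve hits ``rise_2100``
    at ``t1`` exactly.
    """
    if rise_2100 < 0:
        raise ValueError("rise_2100 must be >= 0")
    if exponent < 1:
        raise ValueError("exponent must be >= 1 (decelerating curves unsupported)")
    years = _year_grid(t0, t1, step)
    s = (years - t0) / (t1 - t0)
    meta = {"mode": "parametric", "exponent": exponent, "rise_2100_mm": rise_2100}
    if name:
        meta["scenario"] = _canonical_name(name)
    return Trajectory(years, rise_2100 * s**exponent, "sea_level_mm", meta)


def scenario_sea_level(
    scenario: EmissionScenario | str,
    mode: str = "parametric",
    params: SemiEmpiricalParams | None = None,
    exponent: float = 2.0,
    t0: float = 1990.0,
    t1: float = 2100.0,
    step: float = 1.0,
) -> Trajectory:
    """Sea-level trajectory for a named scenario in either generation mode."""
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    if mode == "parametric":
        if scenario.nominal_rise_2100 is None:
            raise ValueError(f"scenario {scenario.name} has no nominal 2100 rise")
        return parametric_sea_level(
            scenario.nominal_rise_2100, exponent, t0, t1, step, name=scenario.name
        )
    if mode == "semi_empirical":
        temp = temperature_trajectory(scenario, t0, t1, step)
        return integrate_sea_level(temp, params)
    raise ValueError(f"unknown sea-level mode {mode!r}")


def average_rate(traj: Trajectory, ta: float, tb: float) -> float:
    """Mean rate of change ``(H(tb) - H(ta)) / (tb - ta)`` with linear interpolation."""
    if not ta < tb:
        raise ValueError("need ta < tb")
    return (traj.at(tb) - traj.at(ta)) / (tb - ta)
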