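"""Typed pipeline configuration with documented defaults and strict key checking.

A fully default :class:`PipelineConfig` runs the whole pipeline end-to-end:
simulate the dissolution experiment, analyse it, build the scenario sea-level
curves, integrate the reef model and tabulate keep-up outcomes.  Unknown keys
anywhere in a config file are rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synth import ExperimentDesign
from .units import ARAGONITE_DENSITY_G_CM3, DEFAULT_FRAMEWORK_POROSITY

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a pipeline config."""


def _build(cls, data: dict, context: str):
    """Construct a dataclass from a mapping, rejecting unknown keys."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if isinstance(val, list):
            val = tuple(tuple(v) if isinstance(v, list) else v for v in val)
        kwargs[f.name] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


@dataclass(frozen=True)
class FitConfig:
    """Nonlinear-fit settings: Gauss–Newton iteration cap and convergence tolerance."""

    max_iter: int = 200
    tol: float = 1e-10


@dataclass(frozen=True)
class UnitsConfig:
    """Mass <-> thickness conversion constants."""

    mineral_density_g_cm3: float = ARAGONITE_DENSITY_G_CM3
    framework_porosity: float = DEFAULT_FRAMEWORK_POROSITY


@dataclass(frozen=True)
class SeaLevelConfig:
    """Sea-level generation: mode, scenario endpoints and semi-empirical constants."""

    mode: str = "parametric"  # {parametric, semi_empirical}
    exponent: float = 2.0
    a_sl: float = 5.6
    b_sl: float = -49.0
    T0: float = -0.41
    t0: float = 1990.0
    t1: float = 2100.0
    step: float = 1.0


@dataclass(frozen=True)
class ReefConfig:
    """Reef-model coefficients, solver settings and keep-up threshold."""

    mode: str = "constant"  # {constant, literal}
    bS_mm_per_y: float = 1.0
    densities: tuple = (("low", 0.75), ("medium", 3.0), ("high", 7.0))
    D_perforate_mm_per_y: float = 10.5
    D_perforate_kg_m2_y: float | None = None  # if set, overrides via unit conversion
    D_imperforate_mm_per_y: float = 0.0
    A0_mm: float = 100.0
    step_y: float = 0.1
    threshold_mm: float = 0.0


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level configuration for :func:`reefdiss.pipeline.run_pipeline`."""

    seed: int = 0
    output_dir: str = "reefdiss_out"
    log_level: str = "INFO"
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    fit: FitConfig = field(default_factory=FitConfig)
    units: UnitsConfig = field(default_factory=UnitsConfig)
    sealevel: SeaLevelConfig = field(default_factory=SeaLevelConfig)
    reef: ReefConfig = field(default_factory=ReefConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sub = {
            "design": ExperimentDesign,
            "fit": FitConfig,
            "units": UnitsConfig,
            "sealevel": SeaLevelConfig,
            "reef": ReefConfig,
        }
        built = {}
        for key, klass in sub.items():
            if key in data:
                built[key] = _build(klass, data.pop(key), key)
        top = _build(cls, data, "config")
        return dataclasses.replace(top, **built)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh)
        cfg = cls.from_dict(data)
        # the design seed follows the top-level seed unless set explicitly
        if "design" not in (data or {}) or "seed" not in (data or {}).get("design", {}):
            cfg = dataclasses.replace(cfg, design=dataclasses.replace(cfg.design, seed=cfg.seed))
        return cfg


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a YAML config (or defaults) and apply keyword overrides."""
    if path is None:
        cfg = PipelineConfig.from_dict(overrides.pop("data", {}) or {})
    else:
        cfg = PipelineConfig.from_yaml(path)
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    if "seed" in overrides:
        cfg = dataclasses.replace(cfg, design=dataclasses.replace(cfg.design, seed=cfg.seed))
    return cfg
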