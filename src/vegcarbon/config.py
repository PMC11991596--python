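"""Pipeline configuration: typed, YAML-serialisable, typo-safe.

Unknown keys anywhere in the config file are rejected rather than ignored,
and a run's resolved config is copied into its output directory so every
result is reproducible from the artefacts alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .casa import CasaConfig
from .synthetic import (ClimateVarParams, DriverParams, NDVIParams,
                        SyntheticScenario, _default_climate, _default_drivers)

__all__ = ["StageToggles", "OpgdSettings", "PipelineConfig", "load_config"]


@dataclass
class StageToggles:
    generate: bool = True
    npp: bool = True
    validate: bool = True
    nep: bool = True
    trend: bool = True
    attribution: bool = True
    opgd: bool = True


@dataclass
class OpgdSettings:
    methods: tuple[str, ...] = ("equal", "quantile", "natural_breaks", "geometric", "std_dev")
    l_min: int = 3
    l_max: int = 10
    min_stratum_size: int = 2
    interactions: bool = True
    significance: str = "ncf"


@dataclass
class PipelineConfig:
    scenario: SyntheticScenario = field(default_factory=SyntheticScenario)
    casa: CasaConfig = field(default_factory=CasaConfig)
    stages: StageToggles = field(default_factory=StageToggles)
    opgd: OpgdSettings = field(default_factory=OpgdSettings)
    significant: float = 0.05
    highly_significant: float = 0.01
    validation_points: int = 100
    output_dir: str = "vegcarbon_run"

    def to_dict(self) -> dict:
        d = {
            "scenario": _scenario_to_dict(self.scenario),
            "casa": self.casa.to_dict(),
            "stages": dataclasses.asdict(self.stages),
            "opgd": dataclasses.asdict(self.opgd),
            "significant": self.significant,
            "highly_significant": self.highly_significant,
            "validation_points": self.validation_points,
            "output_dir": str(self.output_dir),
        }
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _scenario_to_dict(s: SyntheticScenario) -> dict:
    return {
        "shape": list(s.shape),
        "start_year": s.start_year,
        "n_years": s.n_years,
        "seed": s.seed,
        "pixel_size": s.pixel_size,
        "crs": s.crs,
        "climate_params": {k: dataclasses.asdict(v) for k, v in s.climate_params.items()},
        "ndvi_params": dataclasses.asdict(s.ndvi_params),
        "driver_params": {k: {"effects": list(v.effects)} for k, v in s.driver_params.items()},
        "nep_effect_base": s.nep_effect_base,
        "nep_effect_noise_sd": s.nep_effect_noise_sd,
    }


def _check_keys(d: dict, allowed, where: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


def _scenario_from_dict(d: dict) -> SyntheticScenario:
    allowed = {f.name for f in dataclasses.fields(SyntheticScenario)}
    _check_keys(d, allowed, "scenario")
    kwargs = dict(d)
    if "shape" in kwargs:
        kwargs["shape"] = tuple(kwargs["shape"])
    if "climate_params" in kwargs:
        defaults = _default_climate()
        out = {}
        for name, p in kwargs["climate_params"].items():
            if name not in defaults:
                raise ValueError(f"unknown climate variable {name!r}")
            _check_keys(p, {f.name for f in dataclasses.fields(ClimateVarParams)},
                        f"scenario.climate_params.{name}")
            out[name] = dataclasses.replace(defaults[name], **p)
        defaults.update(out)
        kwargs["climate_params"] = defaults
    if "ndvi_params" in kwargs:
        _check_keys(kwargs["ndvi_params"],
                    {f.name for f in dataclasses.fields(NDVIParams)}, "scenario.ndvi_params")
        kwargs["ndvi_params"] = NDVIParams(**kwargs["ndvi_params"])
    if "driver_params" in kwargs:
        defaults = _default_drivers()
        for name, p in kwargs["driver_params"].items():
            if name not in defaults:
                raise ValueError(f"unknown driver {name!r}")
            _check_keys(p, {"effects"}, f"scenario.driver_params.{name}")
            defaults[name] = DriverParams(effects=tuple(p["effects"]))
        kwargs["driver_params"] = defaults
    return SyntheticScenario(**kwargs)


def config_from_dict(d: dict) -> PipelineConfig:
    allowed = {f.name for f in dataclasses.fields(PipelineConfig)}
    _check_keys(d, allowed, "top level")
    kwargs = {}
    if "scenario" in d:
        kwargs["scenario"] = _scenario_from_dict(d["scenario"])
    if "casa" in d:
        kwargs["casa"] = CasaConfig.from_dict(d["casa"])
    if "stages" in d:
        _check_keys(d["stages"], {f.name for f in dataclasses.fields(StageToggles)}, "stages")
        kwargs["stages"] = StageToggles(**d["stages"])
    if "opgd" in d:
        _check_keys(d["opgd"], {f.name for f in dataclasses.fields(OpgdSettings)}, "opgd")
        o = dict(d["opgd"])
        if "methods" in o:
            o["methods"] = tuple(o["methods"])
        kwargs["opgd"] = OpgdSettings(**o)
    for key in ("significant", "highly_significant", "validation_points", "output_dir"):
        if key in d:
            kwargs[key] = d[key]
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline config, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(raw)
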