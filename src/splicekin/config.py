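"""Run configuration: a YAML file with layout/model/acquisition/correlation/
fit/spatial sections.  Unknown keys are rejected so typos fail loudly."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .kinetic_models import GeneLayout, KineticModel, default_reporter_layout, make_model

__all__ = ["RunConfig", "load_config", "default_config"]


@dataclass
class AcquisitionConfig:
    dt: float = 10.0
    duration: float = 5000.0
    n_traces: int = 21
    additive_sd: float = 0.3
    photobleach_halflife: Optional[float] = None
    background_offset: float = 0.0


@dataclass
class CorrelationConfig:
    block_size: int = 16
    baseline_window: tuple = (300.0, 500.0)
    n_boot: int = 1000
    normalize: bool = True
    photobleach_poly_order: int = 3


@dataclass
class FitConfig:
    variants: tuple = ("II.4",)
    max_delay: float = 400.0
    n_draws: int = 4096
    max_starts: int = 6
    slope_window: tuple = (10.0, 40.0)
    n_boot: int = 200


@dataclass
class SpatialConfig:
    pair_radius: float = 0.25
    mode: str = "live"            # live | fish
    bins_max_um: float = 8.0
    bin_width_um: float = 0.5
    n_null: int = 100_000
    exclusion_um: float = 1.0
    D: float = 0.12               # μm²/s, supplied (RICS is out of scope)
    emission_rate: float = 0.05   # particles/s
    splice_lifetime_mean: float = 12.7
    n_frames: int = 50
    frame_interval: float = 3.26
    nucleus_radius: float = 8.0


@dataclass
class RunConfig:
    layout: GeneLayout = field(default_factory=default_reporter_layout)
    model: KineticModel = field(default_factory=lambda: make_model(
        "II.4", v=2.60, splice_mean=267.0, release_mean=116.1, k_init=0.02))
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    correlation: CorrelationConfig = field(default_factory=CorrelationConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "layout": self.layout.to_dict(),
            "model": self.model.to_dict(),
            "acquisition": asdict(self.acquisition),
            "correlation": {**asdict(self.correlation),
                            "baseline_window": list(self.correlation.baseline_window)},
            "fit": {**asdict(self.fit), "variants": list(self.fit.variants),
                    "slope_window": list(self.fit.slope_window)},
            "spatial": asdict(self.spatial),
            "seed": self.seed,
        }


def _build_section(cls, data: dict, name: str):
    known = set(cls.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("baseline_window", "variants", "slope_window"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path: Union[str, Path]) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(data)


def config_from_dict(data: dict) -> RunConfig:
    known = {"layout", "model", "acquisition", "correlation", "fit",
             "spatial", "seed"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    cfg = RunConfig()
    if "layout" in data:
        cfg.layout = GeneLayout.from_dict(data["layout"])
    if "model" in data:
        cfg.model = KineticModel.from_dict(data["model"])
    if "acquisition" in data:
        cfg.acquisition = _build_section(AcquisitionConfig,
                                         data["acquisition"], "acquisition")
    if "correlation" in data:
        cfg.correlation = _build_section(CorrelationConfig,
                                         data["correlation"], "correlation")
    if "fit" in data:
        cfg.fit = _build_section(FitConfig, data["fit"], "fit")
    if "spatial" in data:
        cfg.spatial = _build_section(SpatialConfig, data["spatial"], "spatial")
    if "seed" in data:
        cfg.seed = int(data["seed"])
    return cfg


def default_config() -> RunConfig:
    return RunConfig()


def dump_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
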