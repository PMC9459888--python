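"""YAML experiment configuration and deterministic seed fan-out.

One global seed drives the whole pipeline; each stage derives its own seed
through a documented counter scheme (``SeedSequence((seed, stage_index))``)
so any stage can be rerun in isolation with the identical stream.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fiber import (
    AcousticScene,
    BurstSource,
    FiberLayout,
    InstrumentNoise,
    PulseConfig,
    TreeSpec,
    WindModel,
)

__all__ = ["derive_seed", "STAGES", "ExperimentConfig", "load_config", "save_config",
           "layout_from_dict", "scene_from_dict", "pulse_from_dict"]

STAGES = ("fiber", "simulate", "dataset", "train_temporal", "train_spectral",
          "evaluate", "alarms")


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed below 2**31, a pure function of (seed, stage)."""
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}; stages: {STAGES}")
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence((int(seed), idx)).generate_state(1)[0] % 2**31)


def pulse_from_dict(d: dict | None) -> PulseConfig:
    return PulseConfig(**(d or {}))


def layout_from_dict(d: dict) -> FiberLayout:
    trees = tuple(TreeSpec(**t) for t in d.get("trees", []))
    rest = {k: v for k, v in d.items() if k != "trees"}
    return FiberLayout(trees=trees, **rest)


def _source_from_dict(d: dict) -> BurstSource:
    d = dict(d)
    if "band" in d:
        d["band"] = tuple(d["band"])
    if "duty_pattern" in d:
        d["duty_pattern"] = tuple(d["duty_pattern"])
    return BurstSource(**d)


def scene_from_dict(d: dict) -> AcousticScene:
    wind = d.get("wind")
    noise = d.get("instrument_noise", "default")
    return AcousticScene(
        duration=d["duration"],
        larvae_sources=tuple(_source_from_dict(s) for s in d.get("larvae_sources", [])),
        disturbance_sources=tuple(_source_from_dict(s) for s in d.get("disturbance_sources", [])),
        wind=WindModel(**wind) if wind else None,
        instrument_noise=(InstrumentNoise() if noise == "default"
                          else InstrumentNoise(**noise) if noise else None),
    )


@dataclass
class ExperimentConfig:
    """Fully serializable description of one end-to-end run."""

    seed: int = 0
    out_dir: str = "experiment_out"
    pulse: dict = field(default_factory=dict)
    layout: dict = field(default_factory=dict)
    n_per_class: int = 600
    epochs: int = 6
    batch_size: int = 64
    learning_rate: float = 1e-3
    alarm_duration: float = 30.0
    wind_speeds_mph: tuple[float, ...] = ()
    decision_threshold: float = 0.5
    safety_factor: float = 1.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["wind_speeds_mph"] = list(self.wind_speeds_mph)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "wind_speeds_mph" in d:
            d["wind_speeds_mph"] = tuple(d["wind_speeds_mph"])
        return cls(**d)


def load_config(path) -> ExperimentConfig:
    with open(path) as f:
        return ExperimentConfig.from_dict(yaml.safe_load(f) or {})


def save_config(path, config: ExperimentConfig) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)
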