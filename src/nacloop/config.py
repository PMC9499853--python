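"""Run configuration: one declarative document for a full pipeline run."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Any

import yaml

from .detector import DetectorConfig
from .stimulation import StimulationPolicy
from .synth import SimulationConfig


@dataclass
class AnalysisConfig:
    """Options for the band-power analyses and the evaluation stage."""

    bands: tuple[str, ...] = (
        "delta", "theta", "alpha", "beta", "gamma", "high_gamma", "low_frequency",
    )
    buffet_channels: tuple[str, ...] = ("left_ventral",)
    buffet_window_s: tuple[float, float] = (-2.0, 0.0)
    buffet_baseline: str = "condition_mean"
    ambulatory_pre_window_s: float = 60.0
    stim_guard_s: float = 0.0
    match_window_s: float = 60.0


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs.

    A single ``seed`` governs all stochastic stages (it overrides the
    simulation sub-config's own seed).
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    stimulation: StimulationPolicy = field(default_factory=StimulationPolicy)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        self.simulation = dataclasses.replace(self.simulation, rng_seed=self.seed)


def _encode(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, datetime):
        return obj.isoformat()
    if isinstance(obj, tuple):
        return [_encode(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    return obj


def to_dict(config: RunConfig) -> dict:
    return _encode(config)


def save_yaml(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(config), sort_keys=False))


_TUPLE_FIELDS = {
    "channels", "burst_band_hz", "sleep_delta_band_hz", "detector_band_hz",
    "bands", "buffet_channels", "buffet_window_s",
}


def _build(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name == "start_clock" and isinstance(value, str):
            value = datetime.fromisoformat(value)
        elif f.name in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def from_dict(data: dict) -> RunConfig:
    return RunConfig(
        simulation=_build(SimulationConfig, data.get("simulation", {})),
        detector=_build(DetectorConfig, data.get("detector", {})),
        stimulation=_build(StimulationPolicy, data.get("stimulation", {})),
        analysis=_build(AnalysisConfig, data.get("analysis", {})),
        seed=int(data.get("seed", 0)),
    )


def load_yaml(path: str | Path) -> RunConfig:
    return from_dict(yaml.safe_load(Path(path).read_text()) or {})
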