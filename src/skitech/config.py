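"""Pipeline configuration: one document, defaults matching the shipped
parameter set (240 Hz, order-4 Butterworth at 0.007 of Nyquist, 333-frame
cycles, conv 64x20 + 64x10, pool 4, LSTM 300+200, dropout 0.2, 12 epochs,
batch 40, KNN k=5).  Precedence is CLI flag > config file > defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io import PRESETS, ValidationError
from .model import ModelSpec
from .segmentation import DEFAULT_REFERENCE_CHANNEL, DEFAULT_TARGET_LEN, FilterSpec

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    sample_rate_hz: float = 240.0
    filter: FilterSpec = field(default_factory=FilterSpec)
    reference_channel: str = DEFAULT_REFERENCE_CHANNEL
    target_len: int = DEFAULT_TARGET_LEN
    min_period_frames: int | None = None
    min_prominence_frac: float = 0.3
    model: ModelSpec = field(default_factory=ModelSpec)
    knn_k: int = 5
    sensor_config: str = "whole_body"
    protocol: str = "loso"
    seed: int = 0

    def __post_init__(self):
        if self.sensor_config not in PRESETS:
            raise ValidationError(
                f"unknown sensor configuration {self.sensor_config!r}; "
                f"choose from {sorted(PRESETS)}")
        if self.protocol not in ("loso", "holdout"):
            raise ValidationError(f"unknown protocol {self.protocol!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        if "filter" in d and isinstance(d["filter"], dict):
            d["filter"] = FilterSpec(**d["filter"])
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelSpec.from_dict(d["model"])
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return PipelineConfig(**d)

    @staticmethod
    def load(path) -> "PipelineConfig":
        text = Path(path).read_text()
        return PipelineConfig.from_dict(yaml.safe_load(text) or {})

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **kwargs)
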