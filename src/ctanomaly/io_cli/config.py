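"""Structured pipeline configuration with strict key validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ..backbone.networks import BackboneConfig
from ..backbone.train import TrainConfig
from ..inversion import InversionConfig

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class ScoringConfig:
    norm: str = "l1"
    calibration_scans: int = 1000


@dataclass(frozen=True)
class TriageConfig:
    policy: str = "youden"
    sensitivity_level: float | None = None
    bootstrap_iterations: int = 10_000


@dataclass(frozen=True)
class SimulationConfig:
    block_size: int = 23
    n_readers: int = 2
    reader_median_s: float = 30.0
    reader_sigma: float = 0.3


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    inversion: InversionConfig = field(default_factory=InversionConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    triage: TriageConfig = field(default_factory=TriageConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "backbone": self.backbone.to_dict()}
        for name in ("train", "inversion", "scoring", "triage", "simulation"):
            out[name] = dataclasses.asdict(getattr(self, name))
        return out


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in config section {name!r}: {sorted(unknown)}")
    coerced = dict(section)
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(coerced[f.name])
    return cls(**coerced)


def load_config(path_or_dict) -> PipelineConfig:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)
    sections = {
        "backbone": BackboneConfig,
        "train": TrainConfig,
        "inversion": InversionConfig,
        "scoring": ScoringConfig,
        "triage": TriageConfig,
        "simulation": SimulationConfig,
    }
    unknown = set(raw) - set(sections) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {"seed": int(raw.get("seed", 0))}
    for name, cls in sections.items():
        section = raw.get(name, {})
        if name == "backbone":
            kwargs[name] = _build_backbone(section)
        else:
            kwargs[name] = _build(cls, section, name)
    return PipelineConfig(**kwargs)


def _build_backbone(section: dict) -> BackboneConfig:
    allowed = {"resolution", "style_dim", "z_dim", "channels"}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in config section 'backbone': {sorted(unknown)}")
    channels = {int(k): int(v) for k, v in (section.get("channels") or {}).items()}
    return BackboneConfig(
        resolution=int(section.get("resolution", 64)),
        style_dim=int(section.get("style_dim", 16)),
        z_dim=int(section.get("z_dim", 16)),
        channels=channels,
    )


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
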