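"""Pipeline configuration with strict key validation.

Defaults reproduce the published protocol settings: lambda = 0.1,
mu = 0.2, 40 epochs, gradient threshold 0.01, 150 target frames per cycle.
Unknown keys are rejected so typos never silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .kernel_metric import TrainConfig
from .synthetic import GaitSimConfig


@dataclass
class PreprocessConfig:
    reference_joint: str = "l_ankle"
    target_frames: int = 150
    min_period: int = 5
    max_lag_fraction: float = 0.6


@dataclass
class HierarchyConfig:
    scheme: str = "figure"          # {figure, paper_dim, custom}
    window_length: int | None = None
    n_windows: int = 7


@dataclass
class CVConfig:
    folds: int = 5
    repeats: int = 10
    seed: int = 0


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    hierarchy: HierarchyConfig = field(default_factory=HierarchyConfig)
    metric: TrainConfig = field(default_factory=TrainConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    simulate: GaitSimConfig = field(default_factory=GaitSimConfig)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "hierarchy": HierarchyConfig,
    "metric": TrainConfig,
    "cv": CVConfig,
    "simulate": GaitSimConfig,
}


def _build_section(cls, doc: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(
            f"unknown config key(s) in '{section}': {sorted(unknown)}")
    return cls(**doc)


def config_from_dict(doc: dict) -> PipelineConfig:
    doc = dict(doc or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in doc:
            section = doc.pop(name)
            if not isinstance(section, dict):
                raise ValueError(f"config section '{name}' must be a mapping")
            kwargs[name] = _build_section(cls, section, name)
    if "log_level" in doc:
        kwargs["log_level"] = str(doc.pop("log_level"))
    if doc:
        raise ValueError(f"unknown config key(s): {sorted(doc)}")
    return PipelineConfig(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load YAML (or JSON, a YAML subset) config; None -> defaults."""
    if path is None:
        return PipelineConfig()
    doc = yaml.safe_load(Path(path).read_text())
    return config_from_dict(doc or {})
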