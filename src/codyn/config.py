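"""Pipeline configuration: defaults, YAML round-trip, stable hashing."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import InputError


@dataclass
class PipelineConfig:
    """End-to-end analysis settings.

    Defaults: latency threshold 0.25 OD, 24 h window, alpha = 0.05,
    k = 5 clusters (the number of species in the design), B = 1000
    ``subset`` resamples at fraction 0.5, raw-scale fold-change tests.
    """

    input_dir: str = "."
    output_dir: str = "results"
    latency_threshold: float = 0.25
    window_h: float = 24.0
    interpolate_latency: bool = True
    od_offset: float = 0.0
    alpha: float = 0.05
    bh_correct: bool = False
    cluster_k: int = 5
    bootstrap_B: int = 1000
    bootstrap_method: str = "subset"
    subset_fraction: float = 0.5
    foldchange_scale: str = "raw"
    seed: int = 1

    def __post_init__(self):
        if self.latency_threshold <= 0 or self.window_h <= 0 or not (0 < self.alpha < 1):
            raise InputError("thresholds must be positive and alpha in (0, 1)")
        if self.bootstrap_B < 1:
            raise InputError("bootstrap_B must be >= 1")
        if self.bootstrap_method not in ("subset", "bootstrap"):
            raise InputError(f"unknown bootstrap method {self.bootstrap_method!r}")
        if self.foldchange_scale not in ("raw", "log"):
            raise InputError(f"unknown fold-change scale {self.foldchange_scale!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text, encoding="utf-8")
        return text

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
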