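"""One serializable structure holding every tunable of the pipeline.

A RunConfig round-trips losslessly through YAML and its SHA-256 hash is
embedded in every run artifact so outputs are traceable to settings.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .synthetic import DEFAULT_BAND_RANGES


@dataclass
class RunConfig:
    seed: int = 0
    # generation
    n_datasets: int = 15
    trials_per_emotion: int = 20
    fs: float = 256.0
    epoch_s: float = 15.0
    trial_span_s: float = 45.0
    channels: list = field(default_factory=lambda: [
        "FP1", "FP2", "F3", "F4", "F7", "F8", "Fz", "C3", "C4", "T3", "T4", "Pz",
    ])
    # preprocessing
    band_ranges: dict = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_BAND_RANGES.items()
    })
    band_method: str = "butter"
    notch_hz: float = 50.0
    # nonlinear estimator settings
    nonlinear: dict = field(default_factory=dict)
    # CFS
    n_bins: int = 5
    su_threshold: float = 0.1
    top_k: int = 10
    min_times: int = 20
    per_group_rankings: bool = True
    # evaluation
    classifier: str = "c45"
    cv_folds: int = 10
    cv_total: int = 100
    repeats: int = 10
    test_per_emotion: int = 8

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**(yaml.safe_load(text) or {}))

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def parse_band_ranges(text: str) -> dict:
    """Parse "theta=4-8,alpha=8-13,beta=13-30" into a band-range map."""
    out = {}
    for part in text.split(","):
        name, rng = part.split("=")
        lo, hi = rng.split("-")
        out[name.strip()] = (float(lo), float(hi))
    return out
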