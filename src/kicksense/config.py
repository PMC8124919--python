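"""Pipeline configuration schema.

A single YAML file with per-stage sections; omitted fields fall back to the
deployed defaults (20 Hz cutoff, order 2, threshold 0.3, 300-sample peak
distance, 2 s windows at 25% overlap, batch 64, the published architecture
hyperparameters, …). CLI flags override file values. Every report embeds
the fully resolved configuration as an audit trail.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .candidates import CandidateParams
from .nn.train import TrainConfig
from .synth import SynthConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "runs/latest"
    arch: str = "cnn"  # cnn | lstm | convlstm | svm
    scenarios: tuple[str, ...] = ("segmented_lab", "window_lab", "window_field")
    n_train_sessions: int = 6
    n_lab_test_sessions: int = 3
    n_field_test_sessions: int = 3
    generator: dict = field(default_factory=dict)  # SynthConfig overrides
    candidate: dict = field(default_factory=dict)  # CandidateParams overrides
    train: dict = field(default_factory=dict)  # TrainConfig overrides
    model: dict = field(default_factory=dict)  # architecture hyperparams

    def synth_config(self) -> SynthConfig:
        return SynthConfig(seed=self.seed, **self.generator)

    def candidate_params(self) -> CandidateParams:
        return CandidateParams(**self.candidate)

    def train_config(self) -> TrainConfig:
        return TrainConfig(seed=self.seed, **self.train)

    def resolved(self) -> dict:
        """Fully resolved config (defaults filled in), for report headers."""
        return {
            "seed": self.seed,
            "arch": self.arch,
            "scenarios": list(self.scenarios),
            "n_train_sessions": self.n_train_sessions,
            "n_lab_test_sessions": self.n_lab_test_sessions,
            "n_field_test_sessions": self.n_field_test_sessions,
            "generator": dataclasses.asdict(self.synth_config()),
            "candidate": dataclasses.asdict(self.candidate_params()),
            "train": dataclasses.asdict(self.train_config()),
            "model": dict(self.model),
        }

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "scenarios" in raw:
            raw["scenarios"] = tuple(raw["scenarios"])
        return cls(**raw)
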