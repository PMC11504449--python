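"""Run configuration: schema, defaults, YAML round-trip.

Defaults follow the training protocol: Adam with learning rate 1e-4, batch
size 1, at most 9000 iterations with early stopping when the validation loss
stops decreasing.  The schedule (T and the linear-beta endpoints) and the
module ablation switches are independent fields.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .networks import PRESETS

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # diffusion schedule
    T: int = 1000
    beta_start: float = 1e-4
    beta_end: float = 0.02
    # model
    preset: str = "tiny"
    msfm: bool = True
    nsa: bool = True
    nsa_kernel: int = 3
    # optimisation
    lr: float = 1e-4
    max_iters: int = 9000
    batch_size: int = 1
    val_interval: int = 200
    patience: int = 5          # early stop after this many non-improving evals
    augment: bool = True
    # inference
    ensemble: int = 5
    threshold: float = 0.5
    # seeds
    seed: int = 0
    aug_seed: int = 35

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not (0.0 < self.beta_start <= self.beta_end < 1.0):
            raise ValueError("beta endpoints must satisfy 0 < start <= end < 1")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.nsa_kernel not in (3, 5):
            raise ValueError("nsa_kernel must be 3 or 5")
        if self.lr <= 0 or self.max_iters < 1 or self.batch_size < 1:
            raise ValueError("invalid optimiser settings")
        if self.ensemble < 1:
            raise ValueError("ensemble count must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
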