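"""Run configuration, seeding, and structured logging helpers.

One global seed fans out to per-module seeds through a stable hash, so
modules never share random streams; a run's config hash is attached to every
artifact the CLI writes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import NetworkConfig
from .train_predict import TrainingConfig

__all__ = ["RunConfig", "derive_seed"]


def derive_seed(global_seed: int, module: str) -> int:
    """A per-module seed below 2^31, stable across runs and platforms."""
    digest = hashlib.sha256(f"{global_seed}:{module}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """All pipeline parameters in one serializable place."""

    data_dir: str = "data"
    output_dir: str = "out"
    seed: int = 0
    mask_radius: float = 4.0
    label_radius: float = 3.0
    vote_radius: float = 3.0
    max_dim: int = 100
    dedup_identity: float = 0.70
    split_max_identity: float = 0.35
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "network" in kwargs and isinstance(kwargs["network"], dict):
            kwargs["network"] = NetworkConfig(**kwargs["network"])
        if "training" in kwargs and isinstance(kwargs["training"], dict):
            kwargs["training"] = TrainingConfig(**kwargs["training"])
        if "split_fractions" in kwargs:
            kwargs["split_fractions"] = tuple(kwargs["split_fractions"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def module_seed(self, module: str) -> int:
        return derive_seed(self.seed, module)
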