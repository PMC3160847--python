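"""Run configuration: every tunable of the pipeline in one validated object.

Defaults equal the study parameters (2-bp chain overlap, 100-tag inclusion
threshold, k1 = 500 fine clusters, k2 = 3 shape tiers, B = 100 bootstrap
replicates, 20-nt peak span, 5% peak intensity).  A YAML config file can
override any field; command-line flags win over the file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    min_overlap: int = 2
    min_tags: int = 100
    extend_to: int | None = None
    coordinate_base: int = 0
    k1: int = 500
    k2: int = 3
    ward_dialect: str = "classic"
    B: int = 100
    span: int = 20
    intensity: float = 0.05
    alpha: float = 1.0
    beta: float = 1.0
    smooth: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.min_tags < 1:
            raise ValueError("min_tags must be >= 1")
        if self.coordinate_base not in (0, 1):
            raise ValueError("coordinate_base must be 0 or 1")
        if self.k1 < 1:
            raise ValueError("k1 must be >= 1")
        if self.k2 < 1:
            raise ValueError("k2 must be >= 1")
        if self.ward_dialect not in ("classic", "squared"):
            raise ValueError("ward_dialect must be 'classic' or 'squared'")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.span <= 0:
            raise ValueError("span must be positive")
        if not 0 < self.intensity < 1:
            raise ValueError("intensity must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def as_dict(self) -> dict:
        return asdict(self)
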