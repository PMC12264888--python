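"""Run configuration: defaults, YAML round-trip, and config hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .dataset import ALL_MODALITIES

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """End-to-end analysis settings.

    Defaults mirror the published analysis: 20 components computed with 5
    retained, VIP threshold 1.5 with top-50 features for connectivity
    models and top-30 otherwise, coefficient threshold 0.2 after 0-1
    rescaling, shared consensus at >= 4 models (core >= 6), and unique
    calls requiring support from >= 2 modalities.
    """

    modalities: list[str] = field(default_factory=lambda: list(ALL_MODALITIES))
    n_components: int = 20
    n_retained: int = 5
    n_vip_pairwise: int = 50
    n_vip_regional: int = 30
    vip_threshold: float = 1.5
    beta_threshold: float = 0.2
    min_models_shared: int = 4
    min_models_core: int = 6
    min_modalities_unique: int = 2
    n_shared_predictors: int = 4
    n_unique_predictors: int = 8
    selection_mode: str = "nested"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_retained > self.n_components:
            raise ValueError("n_retained must not exceed n_components")
        for name in ("vip_threshold", "beta_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.selection_mode not in ("nested", "paper"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")

    def n_top(self) -> dict[str, int]:
        from .dataset import PAIRWISE_MODALITIES

        return {
            m: self.n_vip_pairwise if m in PAIRWISE_MODALITIES else self.n_vip_regional
            for m in self.modalities
        }

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
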