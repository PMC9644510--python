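"""Pipeline configuration with YAML round-tripping.

Defaults are the published operating point: 224x224 patches, K=81, the
11..201 step-10 K-search grid, 10 protein-grouped folds and alpha=0.05.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from .patches import DEFAULT_K, DEFAULT_K_GRID, DEFAULT_OD_THRESHOLD, DEFAULT_PATCH_SIZE
from .selection import DEFAULT_F_ENTER, DEFAULT_F_REMOVE

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    patch_size: int = DEFAULT_PATCH_SIZE
    k: int = DEFAULT_K
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    od_threshold: float = DEFAULT_OD_THRESHOLD
    mode: str = "image"  # feature source: whole "image" or top-K "patch" mean
    sda_f_enter: float = DEFAULT_F_ENTER
    sda_f_remove: float = DEFAULT_F_REMOVE
    sda_max_features: int | None = None
    model: str = "svm"
    svm_c_grid: tuple[float, ...] = tuple(2.0**e for e in range(-3, 8))
    svm_gamma_grid: tuple[float, ...] = tuple(2.0**e for e in range(-9, 2))
    rf_tree_grid: tuple[int, ...] = (100, 300, 500)
    dnn_epochs: int = 200
    folds: int = 10
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


_TUPLE_FIELDS = ("k_grid", "svm_c_grid", "svm_gamma_grid", "rf_tree_grid")


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in _TUPLE_FIELDS:
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
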