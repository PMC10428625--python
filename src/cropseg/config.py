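"""YAML run configuration shared by the CLI commands.

One file holds a section per pipeline stage; unknown sections or keys are
rejected so typos fail loudly.  Every section is optional and falls back
to the library defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig
from .synthetic_data import SceneParams
from .training import TrainConfig

_KNOWN_SECTIONS = ("scene", "model", "training", "tiling", "baselines", "seed", "output_dir")

_TILING_KEYS = {"patch_size", "stride", "train_fraction", "val_fraction"}
_BASELINE_KEYS = {"names", "n_iter", "max_pixels", "features", "select_on"}


@dataclass
class RunConfig:
    scene: SceneParams = field(default_factory=SceneParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    tiling: dict = field(
        default_factory=lambda: {
            "patch_size": 256,
            "stride": 128,
            "train_fraction": 0.8,
            "val_fraction": 0.2,
        }
    )
    baselines: dict = field(
        default_factory=lambda: {
            "names": ["rf", "svm", "ksvm", "xgb"],
            "n_iter": 10,
            "max_pixels": 20000,
            "features": "cube",  # "cube" (12 features) or "pca" (3)
            "select_on": "val",
        }
    )
    seed: int = 0
    output_dir: str = "cropseg_out"


def _build_section(cls, data: dict, name: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
    # tuples serialized as lists in YAML
    kwargs = {
        k: tuple(v) if isinstance(cls.__dataclass_fields__[k].default, tuple) else v
        for k, v in data.items()
    }
    return cls(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Parse a YAML config file; missing file or None yields defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - set(_KNOWN_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    cfg = RunConfig()
    if "scene" in raw:
        cfg.scene = _build_section(SceneParams, raw["scene"], "scene")
    if "model" in raw:
        cfg.model = _build_section(ModelConfig, raw["model"], "model")
    if "training" in raw:
        cfg.training = _build_section(TrainConfig, raw["training"], "training")
    for name, allowed in (("tiling", _TILING_KEYS), ("baselines", _BASELINE_KEYS)):
        if name in raw:
            unknown = set(raw[name]) - allowed
            if unknown:
                raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
            getattr(cfg, name).update(raw[name])
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "output_dir" in raw:
        cfg.output_dir = str(raw["output_dir"])
    return cfg
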