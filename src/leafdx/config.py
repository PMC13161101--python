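"""YAML run-configuration and checkpoint I/O."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .architecture import ModelConfig
from .data import AugmentConfig
from .training import TrainConfig


def load_config(path: Path | str | None) -> tuple[ModelConfig, TrainConfig]:
    """Read a YAML file with optional ``model:``/``train:``/``augment:`` blocks."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    model_cfg = ModelConfig(**raw.get("model", {}))
    train_kwargs = dict(raw.get("train", {}))
    if "augment" in raw and raw["augment"] is not None:
        aug = raw["augment"]
        train_kwargs["augment"] = AugmentConfig(**aug) if isinstance(aug, dict) \
            else AugmentConfig()
    train_cfg = TrainConfig(**train_kwargs)
    return model_cfg, train_cfg


def config_hash(model_cfg: ModelConfig, train_cfg: TrainConfig) -> str:
    blob = json.dumps({"model": model_cfg.to_dict(), "train": train_cfg.to_dict()},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def save_checkpoint(model, model_cfg: ModelConfig, path: Path | str) -> None:
    """Weights as an .npz tensor container; the architecture config as YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump({"model": model_cfg.to_dict()}, fh)


def load_checkpoint(path: Path | str):
    """Rebuild the full model from an .npz checkpoint and its YAML sidecar."""
    from .architecture import DualTrackNet

    path = Path(path)
    with open(path.with_suffix(".yaml")) as fh:
        cfg = ModelConfig(**yaml.safe_load(fh)["model"])
    model = DualTrackNet(cfg)
    with np.load(path) as state:
        model.load_state_dict({k: state[k] for k in state.files})
    return model, cfg
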