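"""Run configuration: one hierarchical YAML file, defaults = the published
training recipe, CLI flags override file values."""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "filter": {"low_hz": 10.0, "high_hz": 450.0, "order": 4,
               "apply_to_piezo": True},
    "window": {"length": 200, "step": 100},
    "model": {"dilations": [1, 2, 3], "tcn_filters": 40, "tcn_kernel": 5,
              "pool_size": 40, "n_heads": 6, "n_classes": 5,
              "dropout": 0.5, "lr": 1.0e-4, "batch_size": 72, "epochs": 500},
    "tdc": {"d_z": 160, "decoder_hidden": 209, "alpha": 1.0, "lam": 0.1,
            "k_sub": 5, "kmeans_restarts": 20, "p_refresh": 5,
            "pretrain_epochs": 100, "epochs": 80, "lr": 1.0e-4,
            "batch_size": 72, "head_lr": 1.0e-3, "head_epochs": 200},
    "simulate": {"n_subjects_per_grade": 5, "duration_s": 4.2,
                 "onset_s": 0.4, "activity_s": 2.5,
                 "amp_jitter_sd": 0.02, "band_jitter_sd": 0.01,
                 "muscle": "TA"},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Defaults, overlaid by an optional YAML file, overlaid by overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        cfg = _deep_merge(cfg, loaded)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def dump_config(cfg: dict) -> str:
    """Canonical serialization of the effective config (logged with outputs)."""
    return json.dumps(cfg, indent=2, sort_keys=True)
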