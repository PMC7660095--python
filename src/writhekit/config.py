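"""Pipeline configuration: defaults, YAML loading, hashing.

One nested mapping with a section per pipeline stage. The defaults are the
pipeline's selected operating point — 15 s windows with 10 s overlap,
consensus N = 3, SVM detector — so running the tools with no flags runs that
configuration.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

DEFAULTS: dict[str, dict[str, Any]] = {
    "preprocess": {
        "confidence_threshold": 0.3,
        "sg_window": 31,
        "sg_polyorder": 3,
    },
    "features": {
        "window_length_s": 15.0,
        "overlap_s": 10.0,
        "downsample_epsilon_frac": 0.005,
        "horizontal_distal_positive": True,
    },
    "annotation": {
        "consensus_n": 3,
        "window_wm_threshold": 0.5,
    },
    "detection": {
        "model": "svm_rbf",
        "hyperparameters": {},
        "seed": 42,
    },
    "evaluation": {},
    "simulate": {
        "n_wm": 15,
        "n_om": 15,
        "fps": 60.0,
        "duration_s": 120.0,
        "n_experts": 5,
        "expert_jitter_s": 0.5,
        "seed": 7,
    },
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict[str, dict[str, Any]]:
    """Defaults merged with an optional YAML config file."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ValueError(f"config file {path} must hold a mapping")
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        cfg = _deep_merge(cfg, user)
    return cfg


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a config mapping (for run manifests)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
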