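"""Run configuration: defaults, YAML loading, merging and hashing.

A run config is a nested mapping with one section per pipeline stage; any
value may be overridden from a YAML file or CLI flags.  The effective
config (after merging) is echoed into the run's output directory together
with its hash so every artifact directory is self-describing.
"""

from __future__ import annotations

import copy
import hashlib
import json
from typing import Mapping

import yaml

from .errors import ConfigurationError

DEFAULTS: dict = {
    "simulate": {
        "n_tracks": 50,
        "duration": 24 * 60.0,
        "dt": 1.0,
        "seed": 0,
        "transition_matrix": [[0.8, 0.15, 0.05],
                              [0.15, 0.8, 0.05],
                              [0.2, 0.2, 0.6]],
        "initial_distribution": [1 / 3, 1 / 3, 1 / 3],
    },
    "preprocess": {
        "max_gap": 10.0,
        "split_threshold": 10.0,
        "min_speed": 1.5,
        "min_duration": 60.0,
        "min_displacement": 20.0,
        "window": 60.0,
        "min_points": 50,
    },
    "discover": {
        "k_min": 2,
        "k_max": 8,
        "k": None,  # None: choose by silhouette scan
        "train_fraction": 0.366,
        "train_count": None,
        "seed": 0,
        "cv": 5,
        "grid": {"max_depth": [3, 6],
                 "learning_rate": [0.1, 0.3],
                 "n_estimators": [100, 300]},
    },
    "stats": {
        "max_lag": 30,
        "fit_lag_min": 10.0,
        "fit_lag_max": 30.0,
        "heatmap_lags": [1, 3, 5, 10],
        "angle_bins": 61,
        "zigzag_lag": 1,
    },
}


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key not in out:
            raise ConfigurationError(f"unknown config key {key!r}")
        if isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None, overrides: Mapping | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file and an override map."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ConfigurationError("config file must hold a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a config for artifact provenance."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def dump_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
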