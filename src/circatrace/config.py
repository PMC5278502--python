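"""Run configuration: YAML load/validate/serialize and hashing."""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml

REQUIRED_KEYS = ["seed", "cohort", "response", "rhythms", "respond"]

DEFAULTS: dict = {
    "cohort": {
        "n_cells": 30,
        "class_mix": {"LNv": 0.4, "DN1": 0.35, "DN2": 0.25},
        "rhythmic_fraction": 0.6,
        "sampling_interval_hr": 3.0,
        "duration_hr": 48.0,
    },
    "response": {
        "groups": ["Vehicle", "PDF", "PDF+TTX"],
        "classes": ["LNv", "DN1", "DN2"],
        "n_per_group_class": 12,
        "baseline_hr": 1.0,
        "duration_hr": 8.0,
        "sampling_interval_hr": 1.0,
        "effect": {
            "onset_hr": 1.0,
            "affected_groups": ["PDF"],
            "affected_classes": ["LNv", "DN1"],
            "effect_shape": "ramp",
            "effect_size": 0.1,
            "blocked_by": ["TTX"],
        },
    },
    "stacks": {"enabled": False, "shape": [12, 40, 40], "n_cells": 3,
               "background_level": 10.0, "peak_intensity": 60.0,
               "radius_voxels": 2.5, "mask_threshold_fraction": 0.1},
    "rhythms": {"band_hr": [18.0, 36.0], "order_rule": "n/3",
                "n_frequencies": 2048},
    "respond": {"reference_group": "Vehicle", "family": "panel",
                "alpha": 0.05},
    "report": {"heatmap_window_hr": 24.0, "ceiling": 3.0,
               "render_png": True},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def resolve_config(raw: dict) -> dict:
    """Validate a raw config dict and fill in defaults."""
    missing = [k for k in REQUIRED_KEYS if k not in raw]
    if missing:
        raise ValueError(f"config missing required key(s): {missing}")
    if not isinstance(raw["seed"], int):
        raise ValueError("seed must be an integer")
    cfg = _merge(DEFAULTS, {k: v for k, v in raw.items() if k != "seed"})
    cfg["seed"] = raw["seed"]
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    return resolve_config(raw)


def dump_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    """Stable short hash of the resolved config (for provenance)."""
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
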