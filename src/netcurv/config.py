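"""YAML run configuration: defaults, loading, and resolved-config logging."""

from __future__ import annotations

import copy
import os

import yaml

from .errors import ConfigurationError

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "netcurv_run",
    "rank_by": "signed",
    "cohort": {
        "n_rois": 40,
        "n_subjects_per_group": 20,
        "n_blocks": 4,
        "within_block_mu": 0.25,
        "between_block_mu": 0.1,
        "group_effect": 0.15,
        "noise_sd": 0.05,
        "n_timepoints": None,
        "score_slope": 1.0,
        "score_noise_sd": 0.5,
    },
    "grid": {"start": 0.02, "stop": 0.50, "step": 0.01},
    "curvature": {"frc_variant": "augmented", "orc_alpha": 0.0, "include_orc": False},
    "global_measures": ["avg_frc", "avg_clustering", "modularity"],
    "nodal_measures": ["frc_node"],
    "stats": {"alpha": 0.05, "equal_var": True},
    "decoding": {
        "n_surrogates": 200,
        "pool": "atlas",
        "enriched_rsn": None,
        "enriched_terms": ["memory", "social"],
        "background_terms": ["rest", "baseline"],
        "p_hit": 0.9,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if k not in base:
            raise ConfigurationError(f"unknown config key: {k!r}")
        if isinstance(v, dict) and isinstance(base[k], dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | None) -> dict:
    """Load a YAML config over the defaults; None gives pure defaults."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return _merge(DEFAULTS, data)


def log_resolved(cfg: dict, out_dir: str) -> str:
    """Every run writes the fully resolved configuration next to its outputs."""
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "resolved_config.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
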