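"""Run configuration: YAML-backed, schema-checked, fully defaulted.

The configuration is a nested key-value document with one section per
pipeline stage. Unknown sections or keys are rejected with the offending
key path; every defaultable field has a documented default, so an empty
file is a valid configuration. ``load -> dump -> load`` round-trips to an
identical configuration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import yaml

from .errors import ConfigError

__all__ = ["DEFAULTS", "RunConfig", "load_config", "dump_config"]

DEFAULTS: dict = {
    "vt_pattern": {
        "nominal_mean": 6.0,   # mL/kg
        "nominal_cv": 30.0,    # percent
        "n": 1200,
        "seed": 0,
        "normalize": True,
    },
    "lung_sim": {
        "vt_nominal": 6.0,
        "body_weight": 0.526,  # kg
        "rr": 40.0,            # breaths/min
        "peep": 2.0,           # cmH2O
        "fio2": 0.4,
        "ie_ratio": 0.5,
        "fs": 200.0,           # Hz
        "r_rs": 0.15,
        "e1_rs": 2.0,
        "e2_rs": 0.15,
        "p0": 2.0,
        "noise_sd": 0.2,       # cmH2O on Paw
        "delivery_cv": 1.5,    # percent on V_T
        "n_breaths": 20,
        "seed": 0,
    },
    "breath_mech": {
        "model": "both",            # linear | volume_dependent | both
        "fit_span": "full_cycle",   # full_cycle | inspiratory
        "window_last_s": 30.0,
    },
    "histo_score": {
        "denominator": "all_points",  # all_points | parenchyma_only
        "n_points": 100,
        "n_fields": 10,
    },
    "gene_expr": {
        "reference_gene": "REF36B4",
        "calibrator_groups": ["NV-Sham", "NV-IR"],
        "replicate_sd_qc": 0.5,
    },
    "study_synth": {
        "n_per_group": 6,
        "nv_per_group": 6,
        "body_weight_mean": 0.526,
        "body_weight_sd": 0.117,
        "breaths_per_window": 20,
        "seed": 0,
    },
    "stats_report": {
        "effect_size_d": 1.85,
        "alpha": 0.05,
        "power": 0.8,
        "sides": "two",
        "allocation_ratio": 1.0,
    },
}


def _check_type(path: str, value, default) -> None:
    # bool is an int subclass: check it first
    if isinstance(default, bool):
        if not isinstance(value, bool):
            raise ConfigError(f"{path}: expected bool, got {type(value).__name__}")
    elif isinstance(default, float):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{path}: expected number, got {type(value).__name__}")
    elif isinstance(default, int):
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"{path}: expected int, got {type(value).__name__}")
    elif isinstance(default, str):
        if not isinstance(value, str):
            raise ConfigError(f"{path}: expected str, got {type(value).__name__}")
    elif isinstance(default, list):
        if not isinstance(value, list):
            raise ConfigError(f"{path}: expected list, got {type(value).__name__}")


@dataclass(frozen=True)
class RunConfig:
    sections: dict

    def get(self, path: str):
        """Dotted-path lookup, e.g. ``cfg.get("lung_sim.fs")``."""
        node = self.sections
        for part in path.split("."):
            if not isinstance(node, dict) or part not in node:
                raise ConfigError(f"unknown config path: {path}")
            node = node[part]
        return node

    def section(self, name: str) -> dict:
        return copy.deepcopy(self.sections[name])


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML config; None or an empty file means defaults."""
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        user = loaded

    merged = copy.deepcopy(DEFAULTS)
    for section, content in user.items():
        if section not in merged:
            raise ConfigError(f"unknown config section: {section}")
        if content is None:
            continue
        if not isinstance(content, dict):
            raise ConfigError(f"{section}: expected a mapping of keys")
        for key, value in content.items():
            if key not in merged[section]:
                raise ConfigError(f"unknown config key: {section}.{key}")
            _check_type(f"{section}.{key}", value, merged[section][key])
            merged[section][key] = value
    return RunConfig(sections=merged)


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.sections, fh, sort_keys=True)
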