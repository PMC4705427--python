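"""Pipeline configuration: defaults, YAML loading and schema validation.

Every constant the method leaves open (pseudocount, no-change band, promoter
window, DE thresholds, clustering choices) lives here with its default, so a
run is fully described by one YAML file.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["ConfigError", "default_config", "load_config", "validate_config"]


class ConfigError(ValueError):
    """Configuration fails schema validation; message names the key."""


_DEFAULTS: dict = {
    "seed": 1,
    "simulate": {
        "annotation": {
            "n_genes": 5000,
            "genome_size": 120_000_000,
            "n_chroms": 2,
        },
        "binding": {
            # study group sizes at 1:10 scale
            "n_regions_per_group": {"I": 173, "II": 506, "III": 276},
            "depth": 300_000,
            "fold_pu1": 8.0,
            "fold_h3k27ac": 8.0,
        },
        "expression": {
            "n_samples_per_condition": 3,
            "effect_log2fc": 1.0,
            "noise_sd": 0.1,
            "n_extra_up": 50,
        },
        "cohort": {
            "n_samples": 60,
            "n_clusters": 3,
            "separation": 3.0,
            "marker_gene": "Pu1_marker",
        },
    },
    "thresholds": {
        "fc_tf_min": 4.0,
        "fc_hist_min": 4.0,
        "hist_abs_min": 50.0,
        "no_change_band": 2.0,
        "pseudocount": 1.0,
    },
    "histone": {"width": 800},
    "promoter": {"upstream": 1000, "downstream": 200},
    "assignment": {"max_dist": 50_000},
    "de": {"alpha": 0.05, "fc_min": 1.2, "two_sided_fc": True},
    "clustering": {"k": 3, "n_boot": 100},
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _deep_update(base: dict, override: dict) -> dict:
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Defaults, deep-merged with a YAML file and then explicit overrides."""
    config = default_config()
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must be a YAML mapping")
        _deep_update(config, loaded)
    if overrides:
        _deep_update(config, overrides)
    validate_config(config)
    return config


def _require_positive(config: dict, *path: str) -> None:
    node = config
    for key in path:
        node = node[key]
    if not isinstance(node, (int, float)) or node <= 0:
        raise ConfigError(f"{'.'.join(path)} must be a positive number, got {node!r}")


def validate_config(config: dict) -> None:
    for path in (
        ("thresholds", "fc_tf_min"),
        ("thresholds", "fc_hist_min"),
        ("thresholds", "hist_abs_min"),
        ("thresholds", "no_change_band"),
        ("thresholds", "pseudocount"),
        ("histone", "width"),
        ("promoter", "upstream"),
        ("promoter", "downstream"),
        ("assignment", "max_dist"),
        ("de", "alpha"),
        ("de", "fc_min"),
        ("simulate", "binding", "depth"),
        ("simulate", "binding", "fold_pu1"),
        ("simulate", "binding", "fold_h3k27ac"),
        ("simulate", "cohort", "separation"),
    ):
        _require_positive(config, *path)
    t = config["thresholds"]
    if t["no_change_band"] >= t["fc_tf_min"]:
        raise ConfigError("thresholds.no_change_band must be below thresholds.fc_tf_min")
    if config["de"]["alpha"] > 1:
        raise ConfigError("de.alpha must be at most 1")
    if config["de"]["fc_min"] < 1:
        raise ConfigError("de.fc_min must be at least 1 (linear scale)")
    if config["clustering"]["k"] < 2:
        raise ConfigError("clustering.k must be at least 2")
    if config["clustering"]["n_boot"] < 0:
        raise ConfigError("clustering.n_boot must be non-negative")
    if config["simulate"]["annotation"]["n_genes"] < 1:
        raise ConfigError("simulate.annotation.n_genes must be at least 1")
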