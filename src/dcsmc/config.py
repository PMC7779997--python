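"""Structured configuration: shipped defaults plus user overrides."""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .optics import OpticalProperties

__all__ = ["load_config", "config_hash", "optical_properties_from_config"]


def _deep_update(base: dict, overrides: Mapping) -> dict:
    for key, value in overrides.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            base[key] = _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load the shipped defaults, optionally deep-merged with a user file."""
    with resources.files("dcsmc").joinpath("defaults.yaml").open() as f:
        config = yaml.safe_load(f)
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        config = _deep_update(config, user)
    return config


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str)
    return hashlib.md5(blob.encode()).hexdigest()[:12]


def optical_properties_from_config(config: Mapping,
                                   which: str = "analytical") -> OpticalProperties:
    if which == "analytical":
        entry = config["optics"]["analytical"]
    else:
        entry = config["optics"]["table"][which]
    return OpticalProperties(
        wavelength_nm=float(entry["wavelength_nm"]),
        mu_a=float(entry["mu_a"]),
        mu_sp=float(entry["mu_sp"]),
        n=float(entry.get("n", 1.37)),
    )
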