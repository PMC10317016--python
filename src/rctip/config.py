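"""Layered YAML configuration with strict key validation.

Every tunable of the pipeline lives under one of five sections
(``reservoir``, ``readout``, ``detector``, ``system``, ``evaluation``).
Loading merges user overrides onto the defaults, rejects unknown keys,
and derives a per-stage seed tree from the single root seed so any output
artifact can be regenerated exactly from its config echo.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = ["DEFAULTS", "Config", "load_config", "resolve_config"]

DEFAULTS: dict = {
    "seed": 0,
    "reservoir": {
        "n": 20,
        "leakage": 0.9,
        "bias": 0.0,
        "spectral_radius": 0.9,
        "density": 0.05,
        "input_scaling": 0.1,
        "washout": 50,
    },
    "readout": {
        "beta": 0.1,
        "gamma": 0.01,
        "method": "ridge",  # ridge | rls
        "T_w": 300,
        "stride": 10,
    },
    "detector": {
        "task": "classification",  # classification | regression
        "family": None,  # default per task: random_forest / ridge
        "n_estimators": 200,
        "negatives_per_run": 50,
        "threshold": None,
        "ensemble": False,
        "ensemble_q": 3,
    },
    "system": {
        "name": "lorenz63",  # lorenz63 | coupled_lorenz | ks
        "noise_sd": 0.0,
        "train_length": 1000,
        "test_length": 5000,
        "options": {},
    },
    "evaluation": {
        "n_train": 100,
        "n_test": 30,
        "scale": 1.0,
        "forecast_steps": 300,
    },
}

_RANGES = {
    ("reservoir", "leakage"): (0.0, 1.0),
    ("reservoir", "density"): (0.0, 1.0),
}


@dataclass(frozen=True)
class Config:
    """A resolved configuration tree (defaults merged with overrides)."""

    data: dict

    def __getitem__(self, key: str):
        return self.data[key]

    def seed_for(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        import zlib

        root = np.random.SeedSequence(
            [self.data["seed"], zlib.crc32(stage.encode()) % 2**31])
        return int(root.generate_state(1)[0] % 2**31)


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict) and key != "options":
            if not isinstance(value, dict):
                raise ValueError(f"config section {where} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            default = defaults[key]
            if default is not None and value is not None:
                if isinstance(default, bool) != isinstance(value, bool):
                    raise ValueError(f"config key {where}: expected "
                                     f"{type(default).__name__}")
                if isinstance(default, (int, float)) and not isinstance(
                        value, (int, float)):
                    raise ValueError(f"config key {where}: expected a number, "
                                     f"got {value!r}")
                if isinstance(default, str) and not isinstance(value, str):
                    raise ValueError(f"config key {where}: expected a string")
            out[key] = value
    return out


def _validate(data: dict) -> None:
    for (section, key), (lo, hi) in _RANGES.items():
        v = data[section][key]
        if not lo <= v <= hi:
            raise ValueError(
                f"config key {section}.{key}={v} outside [{lo}, {hi}]")
    if data["reservoir"]["n"] < 1:
        raise ValueError("config key reservoir.n must be >= 1")
    if data["readout"]["stride"] < 1 or (
            data["readout"]["T_w"] % data["readout"]["stride"] != 0):
        raise ValueError("config key readout.stride must divide readout.T_w")


def resolve_config(overrides: dict | None = None) -> Config:
    """Merge overrides onto the defaults and validate the result."""
    data = _merge(DEFAULTS, overrides or {})
    _validate(data)
    return Config(data=data)


def load_config(path) -> Config:
    """Load a YAML config file; an empty file yields all defaults."""
    text = Path(path).read_text()
    overrides = yaml.safe_load(text) or {}
    if not isinstance(overrides, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return resolve_config(overrides)
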