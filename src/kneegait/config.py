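"""Pipeline configuration: YAML file + programmatic overrides.

A single nested mapping drives every stage. Unknown keys are rejected so a
typo in a config file fails loudly instead of silently using a default.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import ConfigError
from .events import DetectionConfig
from .features import FeatureConfig
from .parameters import GaitOptions, PendulumConfig

DEFAULTS: dict = {
    "sampling_rate": 32.0,
    "sensor_height": 0.34,
    "seed": 0,
    "filter": {"order": 4, "cutoff_hz": 15.0},
    "cwt": {"scale": "auto"},
    "detect": {"prominence_frac": 0.5, "min_separation_s": 0.25},
    "pendulum": {"Wp_m": 0.34, "KG": 4.0},
    "excursion": {"cutoff_hz": 4.0, "repair_halfwidth": 1},
    "features": {"n_harmonics": 20, "ml_axis": "y"},
    "classify": {
        "train_fraction": 0.7,
        "n_simulations": 10,
        "classifiers": ["svm_rbf", "knn", "dt", "nb"],
    },
    "io": {"recordings_dir": None, "reference_table": None, "feature_table": None, "out_dir": "."},
}


class PipelineConfig:
    """Validated nested configuration with spec'd defaults.

    Build from a YAML file (:meth:`from_yaml`), a mapping
    (:meth:`from_mapping`) or defaults, then read stage-specific views via
    the ``detection_config`` / ``pendulum_config`` / ... properties.
    """

    def __init__(self, data: dict | None = None):
        self._data = _merge(DEFAULTS, data or {})

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        return cls(data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls(data)

    def override(self, dotted_key: str, value) -> None:
        """Set e.g. ``filter.cutoff_hz`` — CLI flags win over file values."""
        parts = dotted_key.split(".")
        node = self._data
        for p in parts[:-1]:
            if p not in node or not isinstance(node[p], dict):
                raise ConfigError(f"unknown config section {p!r} in {dotted_key!r}")
            node = node[p]
        if parts[-1] not in node:
            raise ConfigError(f"unknown config key {dotted_key!r}")
        node[parts[-1]] = value

    def __getitem__(self, key):
        return self._data[key]

    def as_dict(self) -> dict:
        return copy.deepcopy(self._data)

    @property
    def sampling_rate(self) -> float:
        return float(self._data["sampling_rate"])

    @property
    def sensor_height(self) -> float:
        return float(self._data["sensor_height"])

    @property
    def seed(self) -> int:
        return int(self._data["seed"])

    @property
    def filter_kwargs(self) -> dict:
        return {"order": int(self._data["filter"]["order"]),
                "cutoff": float(self._data["filter"]["cutoff_hz"])}

    @property
    def detection_config(self) -> DetectionConfig:
        scale = self._data["cwt"]["scale"]
        return DetectionConfig(
            scale=scale if scale == "auto" else float(scale),
            prominence_frac=float(self._data["detect"]["prominence_frac"]),
            min_separation_s=float(self._data["detect"]["min_separation_s"]),
        )

    @property
    def pendulum_config(self) -> PendulumConfig:
        return PendulumConfig(
            Wp=float(self._data["pendulum"]["Wp_m"]), KG=float(self._data["pendulum"]["KG"])
        )

    @property
    def gait_options(self) -> GaitOptions:
        cutoff = self._data["excursion"]["cutoff_hz"]
        return GaitOptions(
            repair_halfwidth=int(self._data["excursion"]["repair_halfwidth"]),
            excursion_cutoff_hz=None if cutoff is None else float(cutoff),
        )

    @property
    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            n_harmonics=int(self._data["features"]["n_harmonics"]),
            ml_axis=str(self._data["features"]["ml_axis"]),
        )

    @property
    def classify_settings(self) -> dict:
        return copy.deepcopy(self._data["classify"])

    @property
    def io(self) -> dict:
        return copy.deepcopy(self._data["io"])


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        full = f"{path}{key}"
        if key not in out:
            raise ConfigError(f"unknown config key {full!r}")
        if isinstance(out[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {full!r} must be a mapping")
            out[key] = _merge(out[key], value, f"{full}.")
        else:
            out[key] = value
    return out
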