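"""YAML run configuration: validation and construction of scenario, floor,
body-model and classifier settings for the CLI pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .floor_sim import (
    ActivityEntry,
    FloorModel,
    ScenarioDesign,
    preset_designs,
)


class ConfigError(ValueError):
    """Raised with the offending field path when a config block is invalid."""


@dataclass
class RunConfig:
    """Top-level run configuration.

    ``scenario`` and ``floor`` control the synthetic-data generator;
    ``svm`` and ``semi_supervised`` are forwarded to the classifier;
    ``experiment`` holds the labelling-rate study settings.  ``seed``
    propagates to every stochastic component.
    """

    scenario: ScenarioDesign | None = None
    floor: FloorModel = field(default_factory=FloorModel)
    svm: dict = field(default_factory=dict)
    semi_supervised: dict = field(default_factory=dict)
    experiment: dict = field(
        default_factory=lambda: {
            "rates": [0.2, 0.4, 0.6, 0.8],
            "repeats": 3,
            "split": 0.7,
        }
    )
    seed: int = 0

    def classifier_params(self) -> dict:
        params = {}
        for key in ("C", "c_star", "gamma"):
            if key in self.svm:
                params[key] = self.svm[key]
        for key in ("max_iter", "add_cap", "margin_band", "error_gate",
                    "strict_peer_check", "validate"):
            if key in self.semi_supervised:
                params[key] = self.semi_supervised[key]
        return params


def _build_scenario(block: dict) -> ScenarioDesign:
    if "preset" in block:
        design = preset_designs(block["preset"])
        for key in ("fs", "duration", "noise_sd", "seed",
                    "amplitude_jitter", "position_jitter"):
            if key in block:
                setattr(design, key, block[key])
        return design
    try:
        inventory = [
            ActivityEntry(e["activity"], int(e["count"]),
                          {k: v for k, v in e.items() if k not in ("activity", "count")})
            for e in block["inventory"]
        ]
    except KeyError as exc:
        raise ConfigError(f"scenario.inventory: missing key {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"scenario.inventory: {exc}") from exc
    kwargs = {k: block[k] for k in
              ("fs", "duration", "noise_sd", "seed", "amplitude_jitter",
               "position_jitter", "positions", "walk_path") if k in block}
    if "sensors" not in block:
        raise ConfigError("scenario.sensors: required")
    try:
        return ScenarioDesign(
            inventory=inventory,
            sensors=[tuple(s) for s in block["sensors"]],
            **kwargs,
        )
    except ValueError as exc:
        raise ConfigError(f"scenario: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "floor" in raw:
        try:
            cfg.floor = FloorModel(**raw["floor"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"floor: {exc}") from exc
    if "scenario" in raw:
        cfg.scenario = _build_scenario(raw["scenario"])
        if cfg.scenario.seed is None:
            cfg.scenario.seed = cfg.seed
    for key in ("svm", "semi_supervised", "experiment"):
        if key in raw:
            block = raw[key]
            if not isinstance(block, dict):
                raise ConfigError(f"{key}: expected a mapping")
            getattr(cfg, key).update(block)
    if "C" in cfg.svm and cfg.svm["C"] <= 0:
        raise ConfigError("svm.C: must be positive")
    return cfg
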