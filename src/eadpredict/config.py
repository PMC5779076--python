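"""YAML configuration: pacing, solver and intervention settings.

The bundled ``data/default_config.yaml`` holds the standard protocol; a
user file overrides any subset of its keys.  Changing the Hill coefficient
away from 1 is allowed but logged — the block model is only calibrated for
coefficient 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .params import PacingProtocol, SolverSettings
from .thresholds import InterventionSpec

logger = logging.getLogger(__name__)


@dataclass
class Config:
    pacing: PacingProtocol
    solver: SolverSettings
    interventions: dict
    hill_coefficient: float = 1.0


def _deep_merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        if key not in base:
            raise KeyError(f"unknown configuration key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(base[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> Config:
    """Defaults, optionally overridden by a user YAML file."""
    raw = yaml.safe_load(
        resources.files("eadpredict").joinpath("data", "default_config.yaml").read_text()
    )
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        raw = _deep_merge(raw, user)

    pacing = PacingProtocol(
        period=raw["pacing"]["period_ms"],
        stimulus_duration=raw["pacing"]["stimulus_duration_ms"],
        stimulus_amplitude=raw["pacing"]["stimulus_amplitude_uA_per_uF"],
        stimulus_offset=raw["pacing"]["stimulus_offset_ms"],
    )
    solver = SolverSettings(
        rtol=raw["solver"]["rtol"],
        atol=raw["solver"]["atol"],
        output_dt=raw["solver"]["output_dt_ms"],
        steady_state_norm=raw["solver"]["steady_state_norm"],
        max_paces=raw["solver"]["max_paces"],
        max_dt=raw["solver"]["max_dt_ms"],
    )
    interventions = {
        kind: InterventionSpec(
            kind=kind,
            interval=tuple(cfg["interval"]),
            eads_at_high=cfg["eads_at_high"],
            gap=cfg["gap"],
        )
        for kind, cfg in raw["interventions"].items()
    }
    hill = float(raw.get("hill_coefficient", 1.0))
    if hill != 1.0:
        logger.warning("Hill coefficient overridden to %g (calibrated value is 1)", hill)
    return Config(pacing=pacing, solver=solver, interventions=interventions,
                  hill_coefficient=hill)
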