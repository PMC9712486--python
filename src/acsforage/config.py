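"""Plain-text (YAML) scenario configuration files.

A config file mirrors the three parameter groups::

    mode: ACS
    landscape: {L: 2000, k: 4, g: 160, u: 0.16}
    movement:  {d_min: 0.01, d_max: 1.0, alpha: 3, h: 200, p: 1, c: 1}
    simulation:
      n_individuals: 80
      total_steps: 10000
      analysis_window: 2000
      init_delta_s: 500
      init_placement: within_clusters
      seed: 1

Omitted keys take the standard defaults.  ``g`` may be given as a string
expression such as ``"80*sqrt(2)"`` so the equal-area geometries stay exact.
"""

from __future__ import annotations

import math
from dataclasses import asdict
from pathlib import Path

import yaml

from .engine import SimulationConfig
from .landscape import ConfigurationError, LandscapeSpec
from .movement import MovementParams
from .scenarios import MODES, ScenarioConfig

__all__ = ["load_config", "save_config"]


def _parse_number(value):
    if isinstance(value, str):
        allowed = {"sqrt": math.sqrt, "pi": math.pi}
        try:
            return float(eval(value, {"__builtins__": {}}, allowed))  # noqa: S307
        except Exception as exc:
            raise ConfigurationError(f"cannot parse numeric expression {value!r}") from exc
    return value


def load_config(path) -> ScenarioConfig:
    """Read a scenario configuration from a YAML file."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    mode = data.get("mode", "ACS")
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}")
    land = dict(data.get("landscape", {}))
    if "g" in land:
        land["g"] = _parse_number(land["g"])
    landscape = LandscapeSpec(**land)
    movement = MovementParams(**data.get("movement", {}))
    sim = SimulationConfig(**data.get("simulation", {}))
    label = data.get("label", f"{mode}_k{landscape.k}_u{landscape.u:g}")
    return ScenarioConfig(
        label=label, mode=mode, landscape=landscape, movement=movement, sim=sim
    )


def save_config(path, scenario: ScenarioConfig):
    """Write a scenario configuration to a YAML file."""
    data = {
        "label": scenario.label,
        "mode": scenario.mode,
        "landscape": {
            "L": scenario.landscape.L,
            "k": scenario.landscape.k,
            "g": scenario.landscape.g,
            "u": scenario.landscape.u,
        },
        "movement": asdict(scenario.movement),
        "simulation": asdict(scenario.sim),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
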