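"""Analysis configuration: YAML/JSON loading, validation and model building.

A config file has four blocks: ``model`` (which built-in model, its
constants and initial conditions), ``protocol`` (observation times,
components, noise), ``seed`` (master seed; per-task seeds are derived by
fixed offsets) and ``analyses`` (which diagnostics to run, with their
options).  ``resolve_config`` fills in every default so the effective
configuration can be echoed next to the results and re-run verbatim.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .core import DynamicalModel
from .models import (
    LnasConstants,
    generate_weather,
    make_epidemics_model,
    make_lnas_model,
)
from .observation import NoiseSpec, ObservationProtocol

__all__ = [
    "ConfigError",
    "load_config",
    "resolve_config",
    "build_model",
    "build_protocol",
    "derive_seed",
]

# fixed offsets so each task draws from an independent stream
SEED_OFFSETS = {
    "dataset": 1,
    "collinearity_mean": 2,
    "are": 3,
    "risk": 4,
    "weather": 5,
}


class ConfigError(ValueError):
    """Invalid or inconsistent analysis configuration."""


_DEFAULTS = {
    "model": {"name": "epidemics"},
    "protocol": None,
    "seed": 0,
    "output_dir": "pracident_out",
    "analyses": {},
}

_EPIDEMICS_PROTOCOL = {
    "times": {"start": 2, "stop": 12, "step": 2},
    "observed": ["I", "N"],
    "noise": {
        "I": {"kind": "relative", "value": 0.015},
        "N": {"kind": "relative", "value": 0.015},
    },
}

_LNAS_PROTOCOL = {
    "times": {"start": 25, "stop": 150, "step": 1},
    "observed": ["Qg", "Qr"],
    "noise": {
        "Qg": {"kind": "absolute", "value": 0.1},
        "Qr": {"kind": "absolute", "value": 0.1},
    },
}

_KNOWN_ANALYSES = {"simulate", "dataset", "collinearity", "profile", "risk", "are"}


def load_config(path) -> dict:
    """Load a YAML (or JSON) config file and resolve its defaults."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return resolve_config(raw)


def resolve_config(raw: dict) -> dict:
    """Fill defaults and validate the analysis blocks."""
    cfg = copy.deepcopy(_DEFAULTS)
    cfg.update(copy.deepcopy(raw))
    model_cfg = cfg["model"]
    if not isinstance(model_cfg, dict) or "name" not in model_cfg:
        raise ConfigError("model block must name a model")
    name = model_cfg["name"]
    if name not in ("epidemics", "lnas"):
        raise ConfigError(f"unknown model {name!r} (expected epidemics or lnas)")
    if cfg["protocol"] is None:
        cfg["protocol"] = copy.deepcopy(
            _EPIDEMICS_PROTOCOL if name == "epidemics" else _LNAS_PROTOCOL
        )
    unknown = set(cfg["analyses"]) - _KNOWN_ANALYSES
    if unknown:
        raise ConfigError(f"unknown analysis blocks: {sorted(unknown)}")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    for block, opts in cfg["analyses"].items():
        if opts is None:
            cfg["analyses"][block] = {}
        elif not isinstance(opts, dict):
            raise ConfigError(f"analysis block {block!r} must be a mapping")
    return cfg


def derive_seed(master: int, task: str) -> int:
    """Per-task seed derived from the master seed by a fixed offset."""
    ss = np.random.SeedSequence([master, SEED_OFFSETS.get(task, 0)])
    return int(ss.generate_state(1)[0] % (2**31))


def build_model(cfg: dict) -> DynamicalModel:
    """Instantiate the configured model (with its weather fixture for LNAS)."""
    m = cfg["model"]
    name = m["name"]
    if name == "epidemics":
        return make_epidemics_model(
            reference=m.get("reference"),
            initial_state=m.get("initial_state"),
            removal_in_I=m.get("removal_in_I", True),
        )
    constants = LnasConstants(**m.get("constants", {}))
    wopts = dict(m.get("weather", {}))
    n_days = wopts.pop("n_days", 151)
    wseed = wopts.pop("seed", derive_seed(cfg["seed"], "weather"))
    weather = generate_weather(n_days, wseed, **wopts)
    return make_lnas_model(
        weather,
        reference=m.get("reference"),
        constants=constants,
        sigma_mode=m.get("sigma_mode", "variate-sd"),
    )


def build_protocol(cfg: dict) -> ObservationProtocol:
    p = cfg["protocol"]
    times = p["times"]
    if isinstance(times, dict):
        times = list(
            np.arange(times["start"], times["stop"] + times.get("step", 1) / 2,
                      times.get("step", 1))
        )
    noise = {
        comp: NoiseSpec(kind=spec["kind"], value=spec["value"])
        for comp, spec in (p.get("noise") or {}).items()
    }
    try:
        return ObservationProtocol(times=times, observed=p["observed"], noise=noise)
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(f"invalid protocol: {exc}") from exc


def dump_effective(cfg: dict, path) -> None:
    """Echo the fully-resolved config next to the outputs."""
    Path(path).write_text(json.dumps(cfg, indent=2, default=str) + "\n")
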