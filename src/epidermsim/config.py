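"""Run configuration: a YAML key-value tree mapped onto the parameter dataclasses.

Example::

    membrane: {kind: sinusoidal, amplitude_um: 50, wavelength_um: 100,
               domain_x_um: 100, domain_y_um: 100}
    lifecycle: {division_period_h: 12}
    forces: {dt_h: 0.02}
    run: {t_total_h: 500, snapshot_every_h: 25, seed: 1}
    calcium: off

A membrane block may instead name a packaged substrate: ``membrane: {preset:
"#255"}``. Validation errors name the offending field path before any compute.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .cell_model import LifecycleParams
from .geometry import ConfigurationError, MembraneSpec
from .mechanics import ForceParams, RunParams, SimConfig

__all__ = ["load_config", "config_from_dict", "ConfigurationError"]


def _build(cls, block: dict, path: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown keys {sorted(unknown)}; allowed: {sorted(allowed)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def config_from_dict(data: dict) -> SimConfig:
    data = dict(data or {})
    mem_block = dict(data.pop("membrane", {}) or {})
    preset = mem_block.pop("preset", None)
    if preset is not None:
        membrane = MembraneSpec.from_preset(
            preset,
            domain_x_um=mem_block.pop("domain_x_um", None),
            domain_y_um=mem_block.pop("domain_y_um", None))
        if mem_block:
            raise ConfigurationError(
                f"membrane: preset {preset!r} does not take extra keys "
                f"{sorted(mem_block)}")
    else:
        membrane = _build(MembraneSpec, mem_block, "membrane")
    life_block = dict(data.pop("lifecycle", {}) or {})
    calcium = data.pop("calcium", None)
    if calcium is not None:
        life_block["calcium_enabled"] = bool(calcium)
    lifecycle = _build(LifecycleParams, life_block, "lifecycle")
    forces = _build(ForceParams, dict(data.pop("forces", {}) or {}), "forces")
    run_block = dict(data.pop("run", {}) or {})
    run_block.pop("out_dir", None)
    run_params = _build(RunParams, run_block, "run")
    if data:
        raise ConfigurationError(f"unknown top-level keys {sorted(data)}")
    return SimConfig(membrane=membrane, lifecycle=lifecycle, forces=forces,
                     run=run_params)


def load_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return config_from_dict(data)
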