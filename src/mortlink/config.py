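"""YAML configuration round-tripping for simulation runs."""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .simulate import GoldSpec, SimulationConfig, SourceSpec, calibrated_config

__all__ = ["load_config", "dump_config", "config_to_dict"]


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["source_specs"] = {sid: asdict(spec)
                         for sid, spec in config.source_specs.items()}
    d["gold_spec"] = asdict(config.gold_spec)
    return d


def _config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    specs = {}
    for sid, sd in (d.pop("source_specs", {}) or {}).items():
        sd = dict(sd)
        sd.setdefault("source_id", sid)
        specs[sid] = SourceSpec(**sd)
    gold = GoldSpec(**(d.pop("gold_spec", {}) or {}))
    return SimulationConfig(source_specs=specs, gold_spec=gold, **d)


def load_config(path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from YAML.

    An empty file (or ``calibrated: true`` with optional overrides of
    ``seed`` and ``n_patients``) yields the calibrated default
    configuration.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if raw.pop("calibrated", False):
        return calibrated_config(seed=raw.get("seed", 0),
                                 n_patients=raw.get("n_patients", 10_000))
    return _config_from_dict(raw)


def dump_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
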