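"""Run configuration: YAML parsing, validation and provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .calibrate import Background
from .network import ExtraSet, NetworkSpec, NeuronParams

__all__ = ["RunConfig", "load_config", "config_hash", "write_sidecar"]

_SECTIONS = {"network", "neuron", "background", "stimulus", "calibration",
             "sweep", "analysis", "synth", "seed", "out_dir"}


class RunConfig:
    """Validated nested configuration for one run.

    Unknown top-level keys or unknown keys inside the typed sections
    are rejected with the offending field path.
    """

    def __init__(self, raw: dict):
        unknown = set(raw) - _SECTIONS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        self.raw = raw
        net = dict(raw.get("network", {}))
        extras = [ExtraSet(**e) for e in net.pop("extra_sets", [])]
        self.network = self._build(NetworkSpec, {**net,
                                                 "extra_sets": tuple(extras)},
                                   "network")
        self.neuron = self._build(NeuronParams, raw.get("neuron", {}),
                                  "neuron")
        self.background = self._build(Background, raw.get("background", {}),
                                      "background")
        self.seed = int(raw.get("seed", 0))
        self.out_dir = Path(raw.get("out_dir", "."))
        self.stimulus = dict(raw.get("stimulus", {}))
        self.calibration = dict(raw.get("calibration", {}))
        self.sweep = dict(raw.get("sweep", {}))
        self.analysis = dict(raw.get("analysis", {}))
        self.synth = dict(raw.get("synth", {}))

    @staticmethod
    def _build(cls, kwargs, section):
        valid = set(cls.__dataclass_fields__)
        unknown = set(kwargs) - valid
        if unknown:
            raise ValueError(
                f"unknown keys in '{section}': {sorted(unknown)}")
        return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(raw)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_sidecar(cfg: RunConfig, out_dir, extra: dict | None = None):
    """Record resolved config, hash and seeds next to the outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": cfg.raw, "config_hash": config_hash(cfg),
            "seed": cfg.seed,
            "network": asdict(cfg.network),
            "neuron": asdict(cfg.neuron),
            "background": asdict(cfg.background)}
    if extra:
        meta.update(extra)
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return out / "meta.json"
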