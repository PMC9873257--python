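"""Run configuration, provenance, and the stage dispatcher.

A :class:`RunConfig` selects one pipeline stage and carries its parameters;
:func:`run_pipeline` executes the stage and writes its output tables plus a
provenance sidecar (config hash, seed, package versions) next to them.
Identical configuration and seed yield byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigError
from .locomotor import ALL_QUADRANTS, Epoch, StimulusProtocol

STAGES = (
    "simulate",
    "locomotor",
    "preference",
    "feeding",
    "calcium",
    "classify",
    "trace",
    "motif",
    "regions",
    "paths",
)


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    ``params`` holds the stage's keyword parameters (window lengths, gap and
    synapse thresholds, generator settings); every parameter has a documented
    default in the corresponding module, so an empty dict runs the stage at
    the published analysis settings.
    """

    stage: str
    seed: int = 0
    inputs: dict[str, str] = field(default_factory=dict)
    output_dir: str = "out"
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ConfigError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stage" not in data:
            raise ConfigError("missing config key: stage")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def protocol_from_dict(data: dict) -> StimulusProtocol:
    """Build a stimulus protocol from a plain mapping (YAML/JSON epoch list)."""
    epochs = []
    for ep in data.get("epochs", []):
        mask = ep.get("quadrant_mask", "ALL")
        mask = ALL_QUADRANTS if mask == "ALL" else frozenset(int(q) for q in mask)
        epochs.append(
            Epoch(
                start=float(ep["start"]),
                end=float(ep["end"]),
                kind=ep.get("kind", "light"),
                intensity=ep.get("intensity", 0.0),
                quadrant_mask=mask,
                pulse=ep.get("pulse", "continuous"),
            )
        )
    return StimulusProtocol(epochs=epochs)


def load_protocol(path) -> StimulusProtocol:
    with open(path) as fh:
        return protocol_from_dict(yaml.safe_load(fh) or {})


def write_provenance(config: RunConfig, out_dir: Path) -> Path:
    record = {
        "config_sha256": config.digest(),
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "bittercircuit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")
    return path


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute one configured stage; returns a map of artifact name → path.

    Every stage writes its tables under ``config.output_dir`` together with
    a ``provenance.json`` sidecar.
    """
    from . import pipeline_stages

    handler = pipeline_stages.HANDLERS.get(config.stage)
    if handler is None:
        raise ConfigError(f"stage {config.stage!r} has no handler")
    for name, path in config.inputs.items():
        if not Path(path).exists():
            raise ConfigError(f"input {name!r} not found: {path}")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = handler(config, out_dir)
    artifacts["provenance"] = write_provenance(config, out_dir)
    return artifacts
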