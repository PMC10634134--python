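"""Run configuration and reproducibility plumbing for the command-line layer.

A run configuration is a plain nested mapping (YAML on disk).  Outputs are
stamped with the master seed and a hash of the canonical configuration, so a
rerun with the same configuration and seed writes byte-identical files
(quadrature engine).  No timestamps are embedded for exactly that reason.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__


@dataclass
class RunConfig:
    """Seed, engine and scenario parameters for one CLI invocation."""

    command: str
    master_seed: int = 0
    engine: str = "quadrature"
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(command=d["command"], master_seed=int(d.get("master_seed", 0)),
                   engine=d.get("engine", "quadrature"), params=dict(d.get("params", {})))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(out_dir, config: RunConfig, extra: dict | None = None) -> Path:
    """Structured manifest written next to every output table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "histborrow",
        "version": __version__,
        "command": config.command,
        "master_seed": config.master_seed,
        "engine": config.engine,
        "config_hash": config_hash(config),
        "params": config.params,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
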