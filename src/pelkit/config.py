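"""Configuration loading and run-manifest provenance."""

from __future__ import annotations

import hashlib
import json
import sys
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

__all__ = ["load_defaults", "load_config", "RunManifest", "file_sha256"]

_KNOWN_SECTIONS = {
    "optics", "blood", "grid", "monte_carlo", "pipeline", "collagen", "phantom",
}


def load_defaults() -> dict:
    """The packaged defaults.toml as a nested dict."""
    ref = resources.files("pelkit.data") / "defaults.toml"
    with ref.open("rb") as fh:
        return tomllib.load(fh)


def load_config(path=None) -> dict:
    """Defaults merged with a user TOML overlay; unknown keys are errors."""
    cfg = load_defaults()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    for section, values in user.items():
        if section not in _KNOWN_SECTIONS:
            raise KeyError(f"unknown config section {section!r}")
        for key, val in values.items():
            if key not in cfg[section]:
                raise KeyError(f"unknown config key {section}.{key}")
            cfg[section][key] = val
    return cfg


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    command: str
    config: dict
    seed: int | None = None
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)
    started: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def add_input(self, path) -> None:
        self.inputs[str(path)] = file_sha256(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = file_sha256(path)

    def write(self, path) -> None:
        from . import __version__

        payload = {
            "command": self.command,
            "package_version": __version__,
            "python": sys.version.split()[0],
            "config": self.config,
            "seed": self.seed,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "started": self.started,
            "finished": datetime.now(timezone.utc).isoformat(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
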