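"""Run configuration: TOML defaults, user overrides, config hashing."""

from __future__ import annotations

import hashlib
import json
import tomllib
from importlib import resources
from pathlib import Path
from typing import Any

__all__ = ["load_defaults", "load_config", "config_hash", "RunConfig"]


def load_defaults() -> dict[str, Any]:
    """The committed default configuration."""
    with resources.files("shipplume.data").joinpath("defaults.toml").open("rb") as fh:
        return tomllib.load(fh)


def _deep_update(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> "RunConfig":
    """Defaults merged with an optional user TOML file."""
    cfg = load_defaults()
    if path is not None:
        with open(path, "rb") as fh:
            cfg = _deep_update(cfg, tomllib.load(fh))
    return RunConfig(cfg)


def config_hash(cfg: dict[str, Any]) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


class RunConfig:
    """Validated view over the merged configuration mapping."""

    VALID_SCENARIOS = ("base", "2XSO3", "T310K", "NUHET", "HSULF")

    def __init__(self, mapping: dict[str, Any]) -> None:
        self.mapping = mapping
        scenario = self.run.get("scenario", "base")
        if scenario not in self.VALID_SCENARIOS:
            raise ValueError(
                f"invalid scenario {scenario!r}; choose from {self.VALID_SCENARIOS}"
            )

    def __getitem__(self, key: str) -> Any:
        return self.mapping[key]

    @property
    def run(self) -> dict[str, Any]:
        return self.mapping.get("run", {})

    @property
    def seed(self) -> int:
        return int(self.run.get("seed", 0))

    @property
    def hash(self) -> str:
        return config_hash(self.mapping)
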