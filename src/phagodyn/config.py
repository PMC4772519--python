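"""Declarative run configuration (YAML) with strict key validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .parameters import PARAM_NAMES

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown or malformed configuration keys."""


_SECTIONS: dict[str, set[str]] = {
    "paths": {"data", "out_dir", "params"},
    "model": {"c_rh0", "horizon", "dt"},
    "fit": {"lower", "upper", "free", "weights"},
    "optimizer": {"n_cells", "tau", "nu", "max_iter", "gtol", "xtol",
                  "fd_rel", "max_outer", "tol", "seed"},
    "scenario": {"name", "switch_time", "horizon", "ko_level"},
}


@dataclass
class RunConfig:
    """Parsed configuration; every section is a plain dict of checked keys."""

    paths: dict[str, Any] = field(default_factory=dict)
    model: dict[str, Any] = field(default_factory=dict)
    fit: dict[str, Any] = field(default_factory=dict)
    optimizer: dict[str, Any] = field(default_factory=dict)
    scenario: dict[str, Any] = field(default_factory=dict)
    source_text: str = ""

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping of sections")
        unknown = set(raw) - set(_SECTIONS)
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
        sections: dict[str, dict[str, Any]] = {}
        for name, allowed in _SECTIONS.items():
            sec = raw.get(name) or {}
            if not isinstance(sec, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            bad = set(sec) - allowed
            if bad:
                raise ConfigError(f"unknown key(s) in section {name!r}: {sorted(bad)}")
            sections[name] = sec
        free = sections["fit"].get("free")
        if free is not None:
            bad = set(free) - set(PARAM_NAMES)
            if bad:
                raise ConfigError(f"unknown parameter(s) in fit.free: {sorted(bad)}")
        return cls(**sections, source_text=text)

    def digest(self) -> str:
        return hashlib.sha256(self.source_text.encode()).hexdigest()[:16]

    def manifest(self, seed: int | None, extras: dict[str, Any] | None = None) -> dict[str, Any]:
        import numpy
        import scipy

        from . import __version__

        m = {
            "config_sha256_16": self.digest(),
            "seed": seed,
            "phagodyn": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        }
        if extras:
            m.update(extras)
        return m

    def write_manifest(self, out_dir: str | Path, seed: int | None,
                       extras: dict[str, Any] | None = None) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "manifest.json"
        path.write_text(json.dumps(self.manifest(seed, extras), indent=2, sort_keys=True) + "\n")
        return path
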