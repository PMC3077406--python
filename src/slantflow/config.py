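"""Run configuration: schema, defaults, YAML/JSON round-trip, table headers."""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .bayes_core import EstimatorConfig

__all__ = ["RunConfig", "load_config", "save_config", "write_table", "read_table"]

_COMMANDS = ("simulate", "gen-data", "estimate", "analyze", "reproduce-figures")
_TOP_KEYS = {"command", "seed", "paths", "estimator", "condition", "design"}

_CONDITION_KEYS = {"label", "regime", "n_subjects", "noise_sd_tan", "k_by_condition"}
_DESIGN_KEYS = {"slant_deg_list", "omega_list_rad_s", "n_replicates", "noisy_def"}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one pipeline run."""

    command: Optional[str] = None
    seed: int = 0
    paths: dict = field(default_factory=dict)
    estimator: Optional[EstimatorConfig] = None
    condition: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.command is not None and self.command not in _COMMANDS:
            raise ValueError(f"unknown command {self.command!r}")
        unknown = set(self.condition) - _CONDITION_KEYS
        if unknown:
            raise ValueError(f"unknown condition config keys: {sorted(unknown)}")
        unknown = set(self.design) - _DESIGN_KEYS
        if unknown:
            raise ValueError(f"unknown design config keys: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "seed": self.seed,
            "paths": dict(self.paths),
            "estimator": self.estimator.to_dict() if self.estimator else None,
            "condition": dict(self.condition),
            "design": dict(self.design),
        }

    @property
    def hash(self) -> str:
        """Short content hash used to stamp output artifacts."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:10]


def _from_dict(d: dict) -> RunConfig:
    unknown = set(d) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    est = d.get("estimator")
    return RunConfig(
        command=d.get("command"),
        seed=int(d.get("seed", 0)),
        paths=d.get("paths", {}) or {},
        estimator=EstimatorConfig.from_dict(est) if est else None,
        condition=d.get("condition", {}) or {},
        design=d.get("design", {}) or {},
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Unknown keys are rejected with an error naming the offending key;
    omitted keys fall back to defaults.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    text = p.read_text()
    data = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return _from_dict(data)


def save_config(config: RunConfig, path) -> None:
    p = Path(path)
    d = config.to_dict()
    if p.suffix == ".json":
        p.write_text(json.dumps(d, indent=2))
    else:
        p.write_text(yaml.safe_dump(d, sort_keys=False))


def _header(seed: int, config_hash: str) -> str:
    from . import __version__

    return f"# slantflow v{__version__} seed={seed} config={config_hash}\n"


def write_table(df: pd.DataFrame, path, seed: int, config_hash: str = "none") -> None:
    """Write a CSV with a provenance header comment (version, seed, config hash)."""
    buf = io.StringIO()
    buf.write(_header(seed, config_hash))
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (header comments skipped)."""
    return pd.read_csv(path, comment="#")
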