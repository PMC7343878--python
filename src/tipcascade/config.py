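"""Experiment configuration: a YAML round-trippable parameter record.

Defaults follow the reference study conditions: populations of N = 100 000
nodes at mean degree K = 10 and ensembles of n = 100 networks.  The
scaled-down experiment kinds override N and n explicitly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError

KINDS = (
    "simulate",
    "threshold-dist",
    "fixedpoints",
    "bifurcation",
    "hysteresis",
    "figure2",
    "figure3",
    "figure4",
)


@dataclass
class ExperimentConfig:
    """Validated parameters for one experiment run."""

    kind: str
    N: int = 100_000
    K: float = 10.0
    link_prob: float | None = None
    rho: float = 0.5
    rho_values: list[float] = field(default_factory=lambda: [0.2, 0.5, 0.8])
    a: float = 0.1
    p: float = 0.56
    n: int = 100
    seed: int = 0
    a_points: int = 30  # log-spaced a grid size for sweep-style experiments
    scan_param: str = "a"
    scan_from: float = 0.0
    scan_to: float = 0.5
    scan_steps: int = 101
    grid_points: int = 10_001
    method: str = "gamma"  # threshold-dist evaluation route
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigError(f"unknown experiment kind {self.kind!r}; expected one of {KINDS}")
        if not (0.0 <= self.a <= self.p <= 1.0):
            raise ConfigError(f"need 0 <= a <= p <= 1, got a={self.a}, p={self.p}")
        if not (0.0 <= self.rho <= 1.0):
            raise ConfigError(f"rho must lie in [0, 1], got rho={self.rho}")
        if self.N < 2:
            raise ConfigError(f"N must be at least 2, got {self.N}")
        if self.n < 1:
            raise ConfigError(f"ensemble size must be positive, got {self.n}")
        if self.scan_param not in ("a", "p", "rho"):
            raise ConfigError(f"scan_param must be one of a, p, rho, got {self.scan_param!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML config; unknown keys are rejected by name."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping of parameters")
    known = {f.name for f in fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    if "kind" not in raw:
        raise ConfigError(f"{path}: missing required key 'kind'")
    return ExperimentConfig(**raw)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
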