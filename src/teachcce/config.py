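"""Experiment configuration: YAML schema, validation, defaults, manifests.

Defaults mirror the standard study conditions: a three-cluster network
of 20-node ER clusters, learning rate 0.9, inverse temperature 0.5 and
a 1000-step round cap.  Unknown keys are rejected rather than ignored,
so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .generations import TEACHER_MODES
from .learning import LearningParams
from .network import DEFAULT_EDGE_PROB

__all__ = ["ExperimentConfig", "NetworkConfig", "RunConfig", "OutputConfig",
           "ConfigError", "parse_config"]


class ConfigError(ValueError):
    """A configuration file or override violates the schema."""


@dataclass(frozen=True)
class NetworkConfig:
    n_clusters: int = 3
    n_per_cluster: int = 20
    edge_prob: float = DEFAULT_EDGE_PROB
    n_goals: int = 6
    goal_clusters: str = "spread"
    path: "str | None" = None  # load a saved network instead of generating

    def __post_init__(self) -> None:
        if self.goal_clusters not in ("spread", "any"):
            raise ConfigError(f"goal_clusters must be 'spread' or 'any', got {self.goal_clusters!r}")
        if self.path is None:
            if self.n_clusters < 1 or self.n_per_cluster < 2:
                raise ConfigError("need n_clusters >= 1 and n_per_cluster >= 2")
            if not 0.0 < self.edge_prob <= 1.0:
                raise ConfigError(f"edge_prob must be in (0, 1], got {self.edge_prob}")
            if self.n_goals < 1:
                raise ConfigError("n_goals must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    R: "int | None" = None
    T: "int | None" = None
    fractions: "tuple[float, ...] | None" = None  # percents of R
    n_generations: int = 100
    n_lineages: int = 100
    n_agents: int = 1000
    teacher_mode: str = "probabilistic"
    teach_last_success: bool = False
    record_every: "int | None" = None

    def __post_init__(self) -> None:
        if self.teacher_mode not in TEACHER_MODES:
            raise ConfigError(f"teacher_mode must be one of {TEACHER_MODES}")
        if self.T is not None and self.fractions is not None:
            raise ConfigError("give either T or fractions, not both")
        if self.R is not None and self.T is not None and not 0 <= self.T < self.R:
            raise ConfigError(f"need 0 <= T < R, got T={self.T}, R={self.R}")
        if self.n_generations < 1 or self.n_lineages < 1 or self.n_agents < 1:
            raise ConfigError("n_generations, n_lineages and n_agents must be >= 1")


@dataclass(frozen=True)
class OutputConfig:
    directory: str = "runs"
    quiet: bool = False


@dataclass(frozen=True)
class ExperimentConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    learning: LearningParams = field(default_factory=LearningParams)
    run: RunConfig = field(default_factory=RunConfig)
    output: OutputConfig = field(default_factory=OutputConfig)
    master_seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def manifest(self) -> str:
        """JSON provenance record: full resolved config + package version."""
        from . import __version__

        return json.dumps(
            {"config": self.to_dict(), "version": __version__}, indent=1, sort_keys=True
        )


_SECTIONS = {
    "network": NetworkConfig,
    "learning": LearningParams,
    "run": RunConfig,
    "output": OutputConfig,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{section}]: {sorted(unknown)}; known: {sorted(known)}"
        )
    if "fractions" in data and data["fractions"] is not None:
        data = dict(data)
        data["fractions"] = tuple(float(x) for x in data["fractions"])
    try:
        return cls(**data)
    except ValueError as exc:
        raise ConfigError(f"[{section}] {exc}") from exc


def parse_config(
    path: "str | Path | None" = None, overrides: "dict | None" = None
) -> ExperimentConfig:
    """Build a validated config from an optional YAML file plus overrides.

    ``overrides`` is a nested dict in the same shape as the file
    (``{"run": {"R": 10}, ...}``); override values win over file values,
    which win over defaults.  Unknown keys anywhere are an error.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must be a mapping")
        data = loaded
    for section, values in (overrides or {}).items():
        if isinstance(values, dict):
            data.setdefault(section, {})
            if not isinstance(data[section], dict):
                raise ConfigError(f"section [{section}] must be a mapping")
            data[section].update({k: v for k, v in values.items() if v is not None})
        else:
            data[section] = values
    unknown = set(data) - set(_SECTIONS) - {"master_seed"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    sections = {
        name: _build_section(cls, dict(data.get(name) or {}), name)
        for name, cls in _SECTIONS.items()
    }
    seed = int(data.get("master_seed", 0))
    return ExperimentConfig(master_seed=seed, **sections)
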