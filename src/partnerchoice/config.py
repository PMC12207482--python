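"""Run configuration: a strict, round-trippable YAML schema.

Every CLI entry point can be driven from a single YAML file mirroring
the library's parameter objects.  Loading is strict — unknown keys and
out-of-range values raise ``ConfigError`` naming the offending field —
and ``save(load(path))`` reproduces the file's content.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .abm import CommunitySpec, EpisodeConfig, InterventionSpec, StagHuntPayoffs
from .model import FocalParams, PopulationParams

__all__ = ["ConfigError", "SweepSettings", "RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass(frozen=True)
class SweepSettings:
    """Grid resolutions for contour sweeps (grids span [0, 1] evenly)."""

    s_points: int = 21
    omega_points: int = 21
    b_points: int = 11
    race_index: int = 8
    mode: str = "analytic"
    n_episodes: int = 10_000

    def __post_init__(self) -> None:
        if self.s_points < 2 or self.omega_points < 2:
            raise ConfigError("sweep: s_points and omega_points must be >= 2")
        if self.b_points < 1:
            raise ConfigError("sweep: b_points must be >= 1")
        if self.mode not in ("analytic", "simulated"):
            raise ConfigError("sweep: mode must be 'analytic' or 'simulated'")


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs: parameters, protocol, seed, logging."""

    seed: int = 0
    focal: FocalParams = field(default_factory=lambda: FocalParams(0.5, 0.5, 0.5))
    population: PopulationParams = field(
        default_factory=lambda: PopulationParams(0.5, 0.5)
    )
    community: CommunitySpec = field(
        default_factory=lambda: CommunitySpec(size=12, training_bias=0.0)
    )
    episode: EpisodeConfig = field(default_factory=EpisodeConfig)
    intervention: InterventionSpec | None = None
    sweep: SweepSettings = field(default_factory=SweepSettings)
    n_episodes: int = 600
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        out = asdict(self)
        # drop community fields that were not set, so round-trips are exact
        comm = out["community"]
        for key in ("training_bias", "rho", "tau"):
            if comm.get(key) is None:
                comm.pop(key)
        if out["intervention"] is None:
            out.pop("intervention")
        elif out["intervention"].get("availability") is None:
            out["intervention"].pop("availability")
        return out

    def hash(self) -> str:
        """Short stable digest of the configuration content."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_SECTIONS = {
    "focal": FocalParams,
    "population": PopulationParams,
    "community": CommunitySpec,
    "episode": EpisodeConfig,
    "intervention": InterventionSpec,
    "sweep": SweepSettings,
}
_PLAIN = {"seed": int, "n_episodes": int, "log_level": str}


def _build(section: str, cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"{section}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{section}: unknown key(s) {sorted(unknown)}")
    if section == "episode" and "payoffs" in data:
        data = dict(data, payoffs=_build("episode.payoffs", StagHuntPayoffs,
                                         data["payoffs"]))
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    """Validate a plain mapping into a ``RunConfig`` (strict keys)."""
    if not isinstance(data, dict):
        raise ConfigError("top level: expected a mapping")
    unknown = set(data) - set(_SECTIONS) - set(_PLAIN)
    if unknown:
        raise ConfigError(f"top level: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, caster in _PLAIN.items():
        if key in data:
            kwargs[key] = caster(data[key])
    for key, cls in _SECTIONS.items():
        if key in data:
            kwargs[key] = _build(key, cls, data[key])
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    return config_from_dict(data or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (inverse of ``load_config``)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
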