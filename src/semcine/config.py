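"""Run configuration and the fixed semantic feature schema."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Sequence

import yaml

#: The eleven clip-level semantic dimensions, in canonical column order.
FEATURE_NAMES: tuple[str, ...] = (
    "motion_intensity",
    "scene_brightness",
    "people_presence",
    "faces_closeup",
    "social_interaction",
    "dialogue",
    "music",
    "valence",
    "arousal",
    "threat",
    "narrative_progress",
)

#: The seven age-adjusted cognitive score columns, in canonical order.
COGNITION_NAMES: tuple[str, ...] = (
    "PMAT24",
    "PicSeq",
    "ListSort",
    "CardSort",
    "Flanker",
    "CogFluidComp",
    "CogCrystalComp",
)


class ConfigError(ValueError):
    """Invalid configuration value or file."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered list of semantic feature names; every feature table column
    must map onto exactly one of these."""

    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ConfigError("feature names must be unique")
        if len(self.names) != 11:
            raise ConfigError(
                f"feature schema must contain exactly 11 names, got {len(self.names)}"
            )

    @property
    def n_features(self) -> int:
        return len(self.names)


DEFAULT_SCHEMA = FeatureSchema()


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline, in seconds where temporal.

    Defaults encode the analysis constants: 1-s TR, 5-s hemodynamic lag,
    20-s target clips with a 16-s minimum and 10-s step, a 5-s terminal
    buffer per movie segment, 20-s rest blocks, ridge penalty 1.0 on the
    standardized scale, 5% per-tail trimmed group mean, 1000 permutations
    and bootstraps, and BH-FDR at q = 0.05.
    """

    tr_seconds: float = 1.0
    lag_seconds: float = 5.0
    clip_target_s: float = 20.0
    clip_min_s: float = 16.0
    clip_step_s: float = 10.0
    end_buffer_s: float = 5.0
    rest_block_s: float = 20.0
    ridge_lambda: float = 1.0
    trim_fraction: float = 0.05
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    fdr_q: float = 0.05
    rng_seed: int = 0
    n_parcels: int = 360
    # advanced switches (documented defaults; see module docs)
    fc_global_mean_removal: bool = False
    pls_center_only: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "tr_seconds",
            "clip_target_s",
            "clip_min_s",
            "clip_step_s",
            "rest_block_s",
            "ridge_lambda",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("lag_seconds", "end_buffer_s"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not (0 <= self.trim_fraction < 0.5):
            raise ConfigError("trim_fraction must lie in [0, 0.5)")
        if not (0 < self.fdr_q < 1):
            raise ConfigError("fdr_q must lie in (0, 1)")
        for name in ("n_permutations", "n_bootstrap", "n_parcels"):
            value = getattr(self, name)
            if not (isinstance(value, int) and value > 0):
                raise ConfigError(f"{name} must be a positive integer")
        if self.clip_min_s > self.clip_target_s:
            raise ConfigError("clip_min_s must not exceed clip_target_s")
        if self.clip_step_s > self.clip_target_s:
            raise ConfigError("clip_step_s must not exceed clip_target_s")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def replace(self, **updates) -> "PipelineConfig":
        data = self.to_dict()
        data.update(updates)
        return PipelineConfig.from_dict(data)

    def hash(self) -> str:
        """Short stable digest of the full configuration, for provenance lines."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def provenance_line(config: PipelineConfig, seed: int | None = None) -> str:
    """Comment line stamped at the top of every output table."""
    tail = "" if seed is None else f" seed={seed}"
    return f"# semcine config_hash={config.hash()}{tail}"
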