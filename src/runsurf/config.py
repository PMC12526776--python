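"""Pipeline configuration: a strict, hashable YAML schema.

One hierarchical file drives every stage (generator, segmentation,
preprocessing, split, model, experiment grid).  Loading is strict:
unknown keys are rejected with a suggestion for the nearest valid key,
values are validated by the owning dataclass (hyperparameters against
the tuning grid, combination names against the sensor table), and
``load(save(c)) == c`` holds exactly.  Every output artifact embeds the
hash of the config that produced it.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Sequence

import yaml

from .layout import COMBINATION_NAMES, SIGNAL_TYPES
from .model import ModelConfig
from .segmentation import (
    DEFAULT_MIN_PROMINENCE_DEG,
    DEFAULT_MIN_SEPARATION_S,
    DEFAULT_TARGET_FRAMES,
)
from .splitting import DEFAULT_FRACTIONS, PROTOCOLS
from .synthetic import DEFAULT_SURFACES, GeneratorConfig, SurfaceParams


class ConfigKeyError(ValueError):
    """An unknown configuration key."""


class ConfigParseError(ValueError):
    """The config file is not valid YAML."""


@dataclass(frozen=True)
class SegmentationConfig:
    mode: str = "cycles"
    target_frames: int = DEFAULT_TARGET_FRAMES
    min_prominence_deg: float = DEFAULT_MIN_PROMINENCE_DEG
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S
    window_s: float = 4.0
    trim_head_frac: float = 0.125
    trim_tail_frac: float = 0.125
    knee: str = "right"

    def __post_init__(self) -> None:
        if self.mode not in ("cycles", "window"):
            raise ValueError(f"segmentation mode must be cycles|window, got {self.mode!r}")
        if self.knee not in ("right", "left"):
            raise ValueError(f"knee must be right|left, got {self.knee!r}")
        if self.target_frames < 2:
            raise ValueError("target_frames must be >= 2")


@dataclass(frozen=True)
class PreprocessingConfig:
    combination: str = "feet"
    signal_type: str = "acceleration"
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.combination not in COMBINATION_NAMES:
            raise ValueError(
                f"combination must be one of {COMBINATION_NAMES}, "
                f"got {self.combination!r}"
            )
        if self.signal_type not in SIGNAL_TYPES:
            raise ValueError(
                f"signal_type must be one of {SIGNAL_TYPES}, "
                f"got {self.signal_type!r}"
            )


@dataclass(frozen=True)
class SplitConfig:
    protocol: str = "subject_dependent"
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    seed: int = 0
    stratify: bool = True

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")
        object.__setattr__(self, "fractions", tuple(self.fractions))


@dataclass(frozen=True)
class ExperimentConfig:
    grid: dict = field(default_factory=dict)
    seeds: tuple[int, ...] = (0,)
    architecture: str = "baseline"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seeds", tuple(self.seeds))
        if self.architecture not in ("baseline", "final"):
            raise ValueError("architecture must be baseline|final")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to replay the pipeline end to end."""

    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    surfaces: tuple[SurfaceParams, SurfaceParams] = DEFAULT_SURFACES
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    output_dir: str = "outputs"

    def __post_init__(self) -> None:
        object.__setattr__(self, "surfaces", tuple(self.surfaces))


def _to_plain(value: Any) -> Any:
    """Dataclasses/tuples/arrays -> YAML-friendly dicts/lists/scalars."""
    if is_dataclass(value) and not isinstance(value, type):
        return {
            f.name: _to_plain(getattr(value, f.name)) for f in fields(value)
        }
    if isinstance(value, (tuple, list)):
        return [_to_plain(v) for v in value]
    if isinstance(value, dict):
        return {k: _to_plain(v) for k, v in value.items()}
    if hasattr(value, "item"):  # numpy scalar
        return value.item()
    return value


def _suggest(key: str, valid: Sequence[str]) -> str:
    close = difflib.get_close_matches(key, valid, n=1)
    hint = f"; did you mean {close[0]!r}?" if close else ""
    return f"unknown config key {key!r}{hint} (valid: {sorted(valid)})"


def _from_plain(cls, data: Any, path: str = ""):
    """Build a dataclass tree from plain dicts, rejecting unknown keys."""
    if not is_dataclass(cls):
        return data
    if not isinstance(data, dict):
        raise ConfigKeyError(f"expected a mapping at {path or 'top level'}")
    valid = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in valid:
            raise ConfigKeyError(_suggest(key, list(valid)) + (f" at {path}" if path else ""))
        kwargs[key] = _coerce_field(valid[key], value, f"{path}.{key}".lstrip("."))
    return cls(**kwargs)


def _coerce_field(f: dataclasses.Field, value: Any, path: str):
    # Nested dataclasses are recognized by their default factory/type.
    nested = {
        "generator": GeneratorConfig,
        "segmentation": SegmentationConfig,
        "preprocessing": PreprocessingConfig,
        "split": SplitConfig,
        "model": ModelConfig,
        "experiment": ExperimentConfig,
    }
    if f.name in nested and isinstance(value, dict):
        return _from_plain(nested[f.name], value, path)
    if f.name == "surfaces":
        return tuple(
            _from_plain(SurfaceParams, s, f"{path}[{i}]") for i, s in enumerate(value)
        )
    if f.name in ("fractions", "seeds", "filters", "cadence_clip_hz",
                  "speed_clip_mps") and isinstance(value, list):
        return tuple(value)
    return value


def to_dict(config: PipelineConfig) -> dict:
    return _to_plain(config)


def from_dict(data: dict) -> PipelineConfig:
    return _from_plain(PipelineConfig, data)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(to_dict(config), sort_keys=False))
    return path


def load_config(path: str | Path) -> PipelineConfig:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" (line {mark.line + 1})" if mark else ""
        raise ConfigParseError(f"malformed config {path}{where}: {exc}") from exc
    if data is None:
        data = {}
    return from_dict(data)


def config_hash(config: PipelineConfig) -> str:
    """Short stable digest of the full configuration."""
    canonical = json.dumps(to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
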