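"""Pipeline configuration: defaults, YAML loading, strict key checking."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .behavior import EthogramConfig
from .focus import FocusConfig
from .optics import OpticsConfig

__all__ = ["TrackingConfig", "BehaviorConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class TrackingConfig:
    """2D linking and occlusion-screening parameters (pixel units).

    Defaults are expressed relative to the nominal 100 px body length at
    30 um/pixel; ``max_gap_s`` is the 'fraction of a second' beyond which a
    mutual overlap is excluded rather than resolved.
    """

    max_link_px: float = 200.0
    patience_frames: int = 5
    area_jump_frac: float = 0.5
    proximity_px: float = 150.0
    max_gap_s: float = 0.5
    min_track_frames: int = 10


@dataclass(frozen=True)
class BehaviorConfig:
    """Behavior-statistics parameters."""

    ethogram: EthogramConfig = field(default_factory=EthogramConfig)
    spatial_bin_mm: tuple[float, float, float] = (0.3, 0.3, 1.0)
    distance_bin_mm: float = 1.0
    vz_thresh_mm_s: float = 50.0
    event_min_frames: int = 3
    vertical_axis: str = "y"


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline driver needs; all defaults load standalone."""

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    focus: FocusConfig = field(default_factory=FocusConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    fps: float = 100.0
    seed: int = 0
    smooth_window_px: int = 5
    opening_diameter_px: float = 10.0
    min_area_px: int = 785
    log_level: str = "INFO"

    @property
    def max_gap_frames(self) -> int:
        return int(round(self.tracking.max_gap_s * self.fps))


_BLOCKS = {
    "optics": OpticsConfig,
    "focus": FocusConfig,
    "tracking": TrackingConfig,
    "behavior": BehaviorConfig,
}


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) under {path}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name == "ethogram":
            value = _build(EthogramConfig, value, f"{path}.{f.name}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config; missing keys fall back to defaults.

    Unknown keys raise immediately.  Keyword overrides replace top-level
    fields after loading (used by CLI flags).
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("config file must contain a mapping")
            data = loaded
    top_names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_names
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, block_cls in _BLOCKS.items():
        if name in data:
            kwargs[name] = _build(block_cls, data[name], name)
    for name in top_names - set(_BLOCKS):
        if name in data:
            kwargs[name] = data[name]
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)
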