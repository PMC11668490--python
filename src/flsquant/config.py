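"""Run configuration, YAML loading and reproducible run manifests.

A :class:`RunConfig` gathers everything a pipeline run needs — input
paths, channel mapping, calibration, thresholding, admission criteria,
tracking parameters, output directory and seed — and is serialized into
every output directory as ``manifest.json`` together with the package
version, so any figure-style output can be re-derived from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .segmentation import FilterCriteria, ThresholdConfig
from .synthetic import DynamicsParams, SceneParams

__all__ = ["RunConfig", "load_config", "write_manifest"]


@dataclass
class RunConfig:
    scene: SceneParams = field(default_factory=SceneParams)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    inputs: list[str] = field(default_factory=list)
    actin_channel: str = "actin"
    probe_channel: str = "probe"
    pixel_size_xy: float | None = None  # override for uncalibrated TIFFs
    z_spacing: float | None = None
    base_slice: int | None = None
    max_step_xy: float = 1.0  # µm, segmentation z-link fallback
    max_link_dist: float = 1.0  # µm, tracking
    min_track_frames: int = 6
    frame_interval: float = 20.0  # s
    out_dir: str = "flsquant_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        self.scene.validate()
        self.dynamics.validate()
        self.threshold.validate()
        self.criteria.validate()
        if self.max_step_xy <= 0 or self.max_link_dist <= 0:
            raise ValueError("link distances must be positive")
        if self.min_track_frames < 1:
            raise ValueError("min_track_frames must be at least 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTION_TYPES = {
    "scene": SceneParams,
    "dynamics": DynamicsParams,
    "threshold": ThresholdConfig,
    "criteria": FilterCriteria,
}


def _build_section(cls, payload: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} option(s): {sorted(unknown)}; "
            f"valid options: {sorted(names)}"
        )
    return cls(**payload)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a validated RunConfig from a YAML file plus overrides."""
    payload: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        payload = yaml.safe_load(path.read_text()) or {}
        if not isinstance(payload, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
    payload.update({k: v for k, v in overrides.items() if v is not None})

    kwargs: dict = {}
    for key, value in payload.items():
        if key in _SECTION_TYPES:
            kwargs[key] = (
                value if dataclasses.is_dataclass(value)
                else _build_section(_SECTION_TYPES[key], dict(value))
            )
        else:
            kwargs[key] = value
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(kwargs) - valid
    if unknown:
        raise ValueError(
            f"unknown config option(s): {sorted(unknown)}; "
            f"valid options: {sorted(valid)}"
        )
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def write_manifest(out_dir: str | Path, config: RunConfig, stage: str) -> Path:
    """Serialize the resolved config + tool version into the output tree."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "flsquant",
        "version": __version__,
        "stage": stage,
        "config": config.to_dict(),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
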