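"""YAML <-> dataclass configuration plumbing for the CLI.

A run config mirrors the config dataclasses section by section::

    acquisition: {shape: [16, 16, 12], t: 50, tr: 2.0}
    signal:      {blob_center: [8, 8, 6], blob_radius: 3.0, ...}
    noise:       {white_sd: 0.5, drift_amp: 0.3, ...}
    preprocess:  {band_low: 0.01, band_high: 0.1, fd_threshold: 0.2}
    spatial:     {channels_per_kernel: 4, d1: 16, ...}
    temporal:    {hidden_units: 32}
    window:      {t: 50, w: 10, s: 1}
    gbdt:        {n_trees: 100, max_depth: 3, learning_rate: 0.1}
    train:       {learning_rate: 0.001, batch_size: 32, epochs: 50}

Missing sections/keys fall back to the dataclass defaults.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .pipeline import GBDTConfig, PipelineConfig, TrainConfig
from .preprocess import PreprocConfig
from .spatial import SpatialEncoderConfig
from .synthetic import AcquisitionSpec, ClassSignalSpec, NoiseSpec
from .temporal import TemporalEncoderConfig, WindowConfig

__all__ = ["load_run_config", "pipeline_config_from_dict", "dump_run_config"]

_TUPLE_KEYS = {"shape", "voxel_size", "blob_center", "kernel_sizes"}


def _build(cls, section: dict | None):
    section = dict(section or {})
    for key in list(section):
        if key in _TUPLE_KEYS and isinstance(section[key], list):
            section[key] = tuple(section[key])
    return cls(**section)


def pipeline_config_from_dict(cfg: dict) -> PipelineConfig:
    return PipelineConfig(
        spatial=_build(SpatialEncoderConfig, cfg.get("spatial")),
        temporal=_build(TemporalEncoderConfig, cfg.get("temporal")),
        window=_build(WindowConfig, cfg.get("window")),
        gbdt=_build(GBDTConfig, cfg.get("gbdt")),
        train=_build(TrainConfig, cfg.get("train")),
    )


def load_run_config(path: Path | str) -> dict:
    """Parse a YAML run config into the config dataclasses."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return {
        "acquisition": _build(AcquisitionSpec, raw.get("acquisition")),
        "signal": _build(ClassSignalSpec, raw.get("signal")),
        "noise": _build(NoiseSpec, raw.get("noise")),
        "preprocess": _build(PreprocConfig, raw.get("preprocess")),
        "pipeline": pipeline_config_from_dict(raw),
        "cohort": raw.get("cohort", {}),
    }


def dump_run_config(configs: dict, path: Path | str) -> Path:
    """Write the resolved configuration back out as YAML."""
    out = {}
    for key, value in configs.items():
        out[key] = asdict(value) if hasattr(value, "__dataclass_fields__") else value
    path = Path(path)
    path.write_text(yaml.safe_dump(out, sort_keys=True))
    return path
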