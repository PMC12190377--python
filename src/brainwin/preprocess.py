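"""In-scope preprocessing chain for 4D volume time series.

Stages, in order: intensity normalization -> global signal regression ->
band-pass filtering, plus framewise-displacement (FD) motion QC. Spatial
registration, slice-timing and motion *correction* are delegated to
upstream tools; this module assumes already-aligned volumes (the synthetic
generator produces them aligned).

Numerical notes
---------------
* Intensity normalization is a global z-score over all in-mask voxels and
  time points (per-voxel temporal z-scoring available via a flag).
* GSR regresses an intercept plus the in-mask mean series out of every
  voxel by least squares; residuals are exactly orthogonal to the global
  signal.
* The band-pass is a 4th-order Butterworth applied forward-backward
  (zero phase). ``filtfilt`` edge padding requires ``t >= 28`` frames.
* FD is the Power convention: sum of absolute frame-to-frame differences
  of the three translations (mm) plus ``head_radius`` times the three
  rotation differences (radians), head radius 50 mm by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .core import SubjectRecord, Volume4D

__all__ = [
    "PreprocConfig",
    "FDSeries",
    "intensity_normalize",
    "global_signal_regress",
    "bandpass_filter",
    "framewise_displacement",
    "apply_qc",
    "preprocess_subject",
    "MIN_TIMEPOINTS",
]

#: Minimum series length accepted by :func:`bandpass_filter` — the
#: forward-backward filter pads with 3 * (2 * order + 1) = 27 samples.
MIN_TIMEPOINTS = 28


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing parameters.

    band_low / band_high:
        Pass-band edges in Hz; the resting-state default keeps 0.01-0.1 Hz.
    fd_threshold:
        Mean-FD exclusion threshold in mm; subjects strictly above it fail QC.
    head_radius:
        Radius (mm) converting rotation angles to arc displacement in FD.
    """

    band_low: float = 0.01
    band_high: float = 0.1
    fd_threshold: float = 0.2
    head_radius: float = 50.0
    filter_order: int = 4
    per_voxel_normalize: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError("need 0 < band_low < band_high")
        if self.fd_threshold <= 0:
            raise ValueError("fd_threshold must be positive")
        if self.head_radius <= 0:
            raise ValueError("head_radius must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


@dataclass(frozen=True)
class FDSeries:
    """Per-transition framewise displacement (mm), length T - 1."""

    values: np.ndarray
    mean_fd: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("FD values must be non-negative")


def intensity_normalize(vol: Volume4D, per_voxel: bool = False) -> Volume4D:
    """Z-score in-mask intensities; out-of-mask voxels are zeroed.

    Global mode (default) centers and scales by the grand in-mask mean and
    sd over all voxels and time points, removing scanner-level intensity
    offsets while preserving spatial contrast. ``per_voxel`` z-scores each
    voxel's time series separately instead.
    """
    mask = vol.effective_mask()
    data = np.zeros_like(vol.data, dtype=np.float64)
    series = vol.data[mask].astype(np.float64)  # (V, T)
    if per_voxel:
        mu = series.mean(axis=1, keepdims=True)
        sd = series.std(axis=1, keepdims=True)
        if np.any(sd <= 0):
            raise ValueError("degenerate volume: constant voxel time series")
        data[mask] = (series - mu) / sd
    else:
        mu, sd = series.mean(), series.std()
        if sd <= 0:
            raise ValueError("degenerate volume: zero in-mask intensity variance")
        data[mask] = (series - mu) / sd
    return vol.with_data(data)


def global_signal_regress(vol: Volume4D) -> Volume4D:
    """Regress an intercept + the global (in-mask mean) signal out of every voxel."""
    mask = vol.effective_mask()
    series = vol.data[mask].astype(np.float64)  # (V, T)
    g = series.mean(axis=0)
    if np.std(g) <= 1e-15:
        raise ValueError("constant global signal; nothing to regress")
    design = np.column_stack([np.ones_like(g), g])  # (T, 2)
    beta, *_ = np.linalg.lstsq(design, series.T, rcond=None)
    resid = series.T - design @ beta  # (T, V)
    data = np.zeros_like(vol.data, dtype=np.float64)
    data[mask] = resid.T
    return vol.with_data(data)


def bandpass_filter(vol: Volume4D, cfg: PreprocConfig) -> Volume4D:
    """Zero-phase Butterworth band-pass of every in-mask voxel series."""
    nyq = 0.5 / vol.tr
    if cfg.band_high >= nyq:
        raise ValueError(
            f"band_high {cfg.band_high} Hz is at or above Nyquist {nyq} Hz "
            f"for tr={vol.tr} s"
        )
    padlen = 3 * (2 * cfg.filter_order + 1)
    if vol.t <= padlen:
        raise ValueError(
            f"need more than {padlen} time points for the zero-phase filter, got {vol.t}"
        )
    b, a = sps.butter(cfg.filter_order, [cfg.band_low, cfg.band_high],
                      btype="band", fs=1.0 / vol.tr)
    mask = vol.effective_mask()
    series = vol.data[mask].astype(np.float64)
    filtered = sps.filtfilt(b, a, series, axis=1)
    data = np.zeros_like(vol.data, dtype=np.float64)
    data[mask] = filtered
    return vol.with_data(data)


def framewise_displacement(trace: np.ndarray, cfg: PreprocConfig) -> FDSeries:
    """Power-style FD: |Δdx|+|Δdy|+|Δdz| + r·(|Δα|+|Δβ|+|Δγ|)."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError(f"motion trace must be (T, 6), got {trace.shape}")
    if trace.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    delta = np.abs(np.diff(trace, axis=0))
    fd = delta[:, :3].sum(axis=1) + cfg.head_radius * delta[:, 3:].sum(axis=1)
    return FDSeries(values=fd, mean_fd=float(fd.mean()))


def apply_qc(
    records: Sequence[SubjectRecord],
    fd_by_subject: Mapping[str, FDSeries],
    cfg: PreprocConfig,
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Partition subjects by the mean-FD rule.

    A subject is excluded when mean FD is *strictly greater* than
    ``cfg.fd_threshold`` (exclusion requires the threshold to be exceeded);
    ``mean_fd`` and ``qc_pass`` are filled in on every record.
    """
    retained: list[SubjectRecord] = []
    excluded: list[SubjectRecord] = []
    for rec in records:
        fd = fd_by_subject[rec.subject_id]
        rec.mean_fd = float(fd.mean_fd)
        rec.qc_pass = rec.mean_fd <= cfg.fd_threshold
        (retained if rec.qc_pass else excluded).append(rec)
    return retained, excluded


def qc_report(records: Sequence[SubjectRecord]):
    """QC report as a DataFrame (subject_id, mean_fd, qc_pass)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"subject_id": r.subject_id, "mean_fd": r.mean_fd, "qc_pass": r.qc_pass}
            for r in records
        ]
    )


def preprocess_subject(
    vol: Volume4D,
    trace: np.ndarray,
    cfg: PreprocConfig,
    stage_hook: Optional[Callable[[str, Volume4D], None]] = None,
) -> tuple[Volume4D, FDSeries, bool]:
    """Full chain: normalize -> GSR -> band-pass, plus the FD/QC verdict.

    ``stage_hook(name, volume)`` is called after each stage, in order —
    useful for instrumentation and debugging.
    """
    out = intensity_normalize(vol, per_voxel=cfg.per_voxel_normalize)
    if stage_hook:
        stage_hook("intensity_normalize", out)
    out = global_signal_regress(out)
    if stage_hook:
        stage_hook("global_signal_regress", out)
    out = bandpass_filter(out, cfg)
    if stage_hook:
        stage_hook("bandpass_filter", out)
    fd = framewise_displacement(trace, cfg)
    qc_pass = fd.mean_fd <= cfg.fd_threshold
    return out, fd, qc_pass
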