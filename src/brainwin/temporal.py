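"""Sliding-window segmentation and the LSTM temporal encoder.

The time series of length t is cut into k half-open windows of length w
advanced by stride s, k = floor((t - w) / s) + 1; the window count is kept
odd (for tie-free voting downstream) by dropping the final window when
needed. Each window's per-time-point voxel vectors are fed to an LSTM in
temporal order and the final hidden state is the window's temporal feature
F_tem,j of dimension d2.

At full scale the per-step voxel vector is large (~10^6), so a learned
linear projection to ``input_projection_dim`` can be inserted before the
recurrence and trained jointly; at desk scale the raw voxel vector is fed
directly (projection off by default).

All indices are 0-based with half-open ranges: window j (0-based) covers
[j*s, j*s + w).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._nn import LSTM, Linear, Param
from .core import Volume4D

__all__ = [
    "WindowConfig",
    "WindowSet",
    "TemporalEncoderConfig",
    "TemporalFeatureSet",
    "segment_windows",
    "build_temporal_encoder",
    "extract_temporal_features",
    "TemporalEncoder",
]


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: series length t, window length w, stride s."""

    t: int = 50
    w: int = 10
    s: int = 1
    enforce_odd_k: bool = True

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if self.w > self.t:
            raise ValueError(f"window length w={self.w} exceeds series length t={self.t}")
        if self.s < 1:
            raise ValueError("s must be >= 1")


@dataclass(frozen=True)
class WindowSet:
    """k half-open windows [start, start + w), starts j*s for j = 0..k-1."""

    starts: tuple[int, ...]
    w: int

    @property
    def k(self) -> int:
        return len(self.starts)

    def ranges(self) -> list[tuple[int, int]]:
        return [(st, st + self.w) for st in self.starts]


def segment_windows(cfg: WindowConfig) -> WindowSet:
    """Enumerate sliding windows; drops the last one if k must be odd.

    The raw count is k = floor((t - w) / s) + 1. With ``enforce_odd_k`` an
    even k is decremented by discarding the final window, so all remaining
    starts keep the j*s formula.
    """
    k_raw = (cfg.t - cfg.w) // cfg.s + 1
    starts = tuple(j * cfg.s for j in range(k_raw))
    if cfg.enforce_odd_k and len(starts) % 2 == 0:
        starts = starts[:-1]
    return WindowSet(starts=starts, w=cfg.w)


@dataclass(frozen=True)
class TemporalEncoderConfig:
    """LSTM size; d2 defaults to the hidden width (the final hidden state
    is the feature). ``input_projection_dim`` enables the pre-recurrence
    linear projection."""

    hidden_units: int = 500
    d2: Optional[int] = None
    input_projection_dim: Optional[int] = None

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.d2 is not None and self.d2 != self.hidden_units:
            raise ValueError("d2 must equal hidden_units (final hidden state is the feature)")
        if self.input_projection_dim is not None and self.input_projection_dim < 1:
            raise ValueError("input_projection_dim must be >= 1")

    @property
    def feature_dim(self) -> int:
        return self.hidden_units

    @staticmethod
    def toy() -> "TemporalEncoderConfig":
        return TemporalEncoderConfig(hidden_units=32)


@dataclass
class TemporalFeatureSet:
    """Per-window temporal features: row j is F_tem,j, shape (k, d2)."""

    features: np.ndarray
    starts: tuple[int, ...]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        if self.features.ndim != 2 or self.features.shape[0] != len(self.starts):
            raise ValueError("features must be (k, d2) aligned with starts")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite temporal features")

    @property
    def k(self) -> int:
        return self.features.shape[0]

    @property
    def d2(self) -> int:
        return self.features.shape[1]


class TemporalEncoder:
    """Optional linear input projection followed by a single LSTM layer."""

    def __init__(self, cfg: TemporalEncoderConfig, n_voxels: int, seed: int):
        self.cfg = cfg
        self.n_voxels = int(n_voxels)
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        if cfg.input_projection_dim is not None:
            self.proj: Optional[Linear] = Linear(
                self.n_voxels, cfg.input_projection_dim, rng,
                scale=float(1.0 / np.sqrt(self.n_voxels)),
            )
            lstm_in = cfg.input_projection_dim
        else:
            self.proj = None
            lstm_in = self.n_voxels
        self.lstm = LSTM(lstm_in, cfg.hidden_units, rng)
        self._win_shape: Optional[tuple[int, int]] = None

    @property
    def d2(self) -> int:
        return self.cfg.feature_dim

    def params(self) -> list[Param]:
        out = [] if self.proj is None else list(self.proj.params())
        return out + self.lstm.params()

    def forward(self, windows: np.ndarray, train: bool = False) -> np.ndarray:
        """Map windows ``(B, w, V)`` to features ``(B, d2)``."""
        if windows.ndim != 3 or windows.shape[2] != self.n_voxels:
            raise ValueError(
                f"expected (B, w, {self.n_voxels}) windows, got {windows.shape}"
            )
        x = windows.astype(np.float32, copy=False)
        b, w, v = x.shape
        self._win_shape = (b, w)
        if self.proj is not None:
            x = self.proj.forward(x.reshape(b * w, v), train=train).reshape(b, w, -1)
        return self.lstm.forward(x, train=train)

    def backward(self, dfeat: np.ndarray) -> None:
        dx = self.lstm.backward(dfeat.astype(np.float32, copy=False))
        if self.proj is not None:
            b, w = self._win_shape
            self.proj.backward(dx.reshape(b * w, -1))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {
            "lstm.wx": self.lstm.wx.value,
            "lstm.wh": self.lstm.wh.value,
            "lstm.b": self.lstm.b.value,
        }
        if self.proj is not None:
            state["proj.w"] = self.proj.w.value
            state["proj.b"] = self.proj.b.value
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.lstm.wx.value[...] = state["lstm.wx"]
        self.lstm.wh.value[...] = state["lstm.wh"]
        self.lstm.b.value[...] = state["lstm.b"]
        if self.proj is not None:
            self.proj.w.value[...] = state["proj.w"]
            self.proj.b.value[...] = state["proj.b"]


def build_temporal_encoder(
    cfg: TemporalEncoderConfig, n_voxels: int, seed: int
) -> TemporalEncoder:
    """Construct a seeded temporal encoder for ``n_voxels`` inputs per step."""
    return TemporalEncoder(cfg, n_voxels, seed)


def extract_temporal_features(
    encoder: TemporalEncoder, vol: Volume4D, windows: WindowSet
) -> TemporalFeatureSet:
    """Encode every window of a subject's (in-mask) voxel time series."""
    voxmat = vol.voxel_matrix()  # (T, V)
    if windows.starts and windows.starts[-1] + windows.w > voxmat.shape[0]:
        raise ValueError(
            f"window [{windows.starts[-1]}, {windows.starts[-1] + windows.w}) "
            f"exceeds series length {voxmat.shape[0]}"
        )
    batch = np.stack([voxmat[st:st + windows.w] for st in windows.starts])
    feats = encoder.forward(batch)
    return TemporalFeatureSet(features=feats, starts=windows.starts)
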