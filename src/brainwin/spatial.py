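"""Multi-scale 3D-CNN spatial encoder.

Each time point's 3D volume X_i is mapped independently to a feature
vector F_sp,i of dimension d1: per layer, parallel same-padded 3D
convolutions at several kernel sizes are concatenated along the channel
axis (multi-scale aggregation), passed through a rectifier and max-pooled;
after the final layer the feature map is flattened and a single fully
connected layer projects to d1. There is no temporal mixing — the encoder
is a pure function of one frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._nn import Linear, MaxPool3d, MultiScaleConv3d, Param, ReLU
from .core import Volume4D

__all__ = [
    "SpatialEncoderConfig",
    "SpatialFeatureSeq",
    "conv_output_shape",
    "build_spatial_encoder",
    "extract_spatial_features",
    "SpatialEncoder",
]


@dataclass(frozen=True)
class SpatialEncoderConfig:
    """Architecture of the spatial encoder.

    Defaults follow the two-layer, kernel-size {3,5,7}, pool-2/stride-2
    design; ``channels_per_kernel`` and ``d1`` are not pinned down by that
    design and are recorded in run metadata. ``toy()`` shrinks both for
    desk-scale work.
    """

    n_layers: int = 2
    kernel_sizes: tuple[int, ...] = (3, 5, 7)
    channels_per_kernel: int = 8
    pool_size: int = 2
    pool_stride: int = 2
    d1: int = 128
    activation: str = "relu"
    padding: str = "same"

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not self.kernel_sizes:
            raise ValueError("need at least one kernel size")
        for k in self.kernel_sizes:
            if k < 3 or k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and >= 3, got {k}")
        if self.pool_size < 1 or self.pool_stride < 1:
            raise ValueError("pool_size and pool_stride must be >= 1")
        if self.d1 < 1:
            raise ValueError("d1 must be >= 1")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")
        if self.padding != "same":
            raise ValueError(f"unsupported padding {self.padding!r}")

    @staticmethod
    def toy() -> "SpatialEncoderConfig":
        return SpatialEncoderConfig(channels_per_kernel=4, d1=16)


@dataclass
class SpatialFeatureSeq:
    """Per-time-point spatial features: row i is F_sp,i, shape (t, d1)."""

    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        if self.features.ndim != 2:
            raise ValueError("features must be a (t, d1) matrix")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite spatial features")

    @property
    def t(self) -> int:
        return self.features.shape[0]

    @property
    def d1(self) -> int:
        return self.features.shape[1]


def conv_output_shape(
    in_shape: Sequence[int],
    kernel: int,
    padding: str = "same",
    pool_size: int = 2,
    pool_stride: int = 2,
) -> tuple[int, int, int]:
    """Spatial shape after one same-padded conv + max-pool stage."""
    if padding != "same":
        raise ValueError(f"unsupported padding {padding!r}")
    if any(d < 1 for d in in_shape):
        raise ValueError(f"invalid input shape {tuple(in_shape)}")
    out = tuple(
        MaxPool3d.out_dim(int(d), pool_size, pool_stride) for d in in_shape
    )
    if any(d < 1 for d in out):
        raise ValueError(
            f"volume too small for config: {tuple(in_shape)} pooled to {out}"
        )
    return out  # same-padded conv preserves dims; pooling floors them


class SpatialEncoder:
    """Built spatial encoder; see module docstring for the architecture."""

    def __init__(self, cfg: SpatialEncoderConfig, in_shape: Sequence[int], seed: int):
        self.cfg = cfg
        self.in_shape = tuple(int(d) for d in in_shape)
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        shape = self.in_shape
        c_in = 1
        self.blocks: list[tuple[MultiScaleConv3d, ReLU, MaxPool3d]] = []
        for _ in range(cfg.n_layers):
            conv = MultiScaleConv3d(c_in, cfg.channels_per_kernel, cfg.kernel_sizes, rng)
            self.blocks.append((conv, ReLU(), MaxPool3d(cfg.pool_size, cfg.pool_stride)))
            shape = conv_output_shape(
                shape, cfg.kernel_sizes[0], cfg.padding, cfg.pool_size, cfg.pool_stride
            )
            c_in = conv.c_out
        self.pooled_shape = shape
        self.flat_dim = c_in * int(np.prod(shape))
        self.fc = Linear(self.flat_dim, cfg.d1, rng)

    @property
    def d1(self) -> int:
        return self.cfg.d1

    def params(self) -> list[Param]:
        out: list[Param] = []
        for conv, _, _ in self.blocks:
            out.extend(conv.params())
        out.extend(self.fc.params())
        return out

    def forward(self, frames: np.ndarray, train: bool = False) -> np.ndarray:
        """Map frames ``(B, X, Y, Z)`` to features ``(B, d1)``."""
        if frames.ndim == 4:
            x = frames[:, None]
        else:
            x = frames
        if x.shape[2:] != self.in_shape:
            raise ValueError(
                f"frame shape {x.shape[2:]} does not match encoder build "
                f"shape {self.in_shape}"
            )
        x = x.astype(np.float32, copy=False)
        for conv, act, pool in self.blocks:
            x = pool.forward(act.forward(conv.forward(x, train=train), train=train),
                             train=train)
        self._pre_flat_shape = x.shape
        flat = x.reshape(x.shape[0], -1)
        return self.fc.forward(flat, train=train)

    def backward(self, dfeat: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(features)."""
        d = self.fc.backward(dfeat.astype(np.float32, copy=False))
        d = d.reshape(self._pre_flat_shape)
        for bi, (conv, act, pool) in reversed(list(enumerate(self.blocks))):
            # the first block's input gradient is never consumed
            d = conv.backward(act.backward(pool.backward(d)), need_dx=bi > 0)

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for li, (conv, _, _) in enumerate(self.blocks):
            for bi, branch in enumerate(conv.branches):
                state[f"block{li}.conv{bi}.w"] = branch.w.value
                state[f"block{li}.conv{bi}.b"] = branch.b.value
        state["fc.w"] = self.fc.w.value
        state["fc.b"] = self.fc.b.value
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for li, (conv, _, _) in enumerate(self.blocks):
            for bi, branch in enumerate(conv.branches):
                branch.w.value[...] = state[f"block{li}.conv{bi}.w"]
                branch.b.value[...] = state[f"block{li}.conv{bi}.b"]
        self.fc.w.value[...] = state["fc.w"]
        self.fc.b.value[...] = state["fc.b"]


def build_spatial_encoder(
    cfg: SpatialEncoderConfig, in_shape: Sequence[int], seed: int
) -> SpatialEncoder:
    """Construct a seeded spatial encoder for volumes of ``in_shape``."""
    return SpatialEncoder(cfg, in_shape, seed)


def extract_spatial_features(
    encoder: SpatialEncoder, vol: Volume4D, batch_frames: int = 25
) -> SpatialFeatureSeq:
    """Apply the encoder to every time point; returns a (t, d1) sequence."""
    if vol.spatial_shape != encoder.in_shape:
        raise ValueError(
            f"volume spatial shape {vol.spatial_shape} does not match "
            f"encoder build shape {encoder.in_shape}"
        )
    frames = np.moveaxis(vol.data, -1, 0).astype(np.float32)  # (T, X, Y, Z)
    rows = [
        encoder.forward(frames[i:i + batch_frames])
        for i in range(0, frames.shape[0], batch_frames)
    ]
    return SpatialFeatureSeq(features=np.concatenate(rows, axis=0))
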