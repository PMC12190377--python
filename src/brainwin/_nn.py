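"""Minimal numpy neural-network kernel: 3D convolution, max-pooling,
linear, rectifier and LSTM layers with hand-written backward passes, plus
an Adam optimizer and a logistic loss.

All layers follow the same discipline: ``forward(x, train=...)`` caches
whatever the backward pass needs only when ``train`` is true;
``backward(dy)`` accumulates parameter gradients in place and returns the
gradient with respect to the layer input. Convolutions are stride-1 with
"same" zero padding and odd kernels, realized as im2col + GEMM; the
input-gradient is the correlation of the output gradient with the
spatially flipped, channel-transposed kernel. Everything is float32 and
deterministic given the seeded ``numpy.random.Generator`` used at
construction.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Linear",
    "Conv3dSame",
    "MultiScaleConv3d",
    "MaxPool3d",
    "ReLU",
    "LSTM",
    "Adam",
    "bce_with_logits",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Module:
    def params(self) -> list[Param]:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        if scale is None:
            scale = float(np.sqrt(2.0 / d_in))
        self.w = Param(rng.normal(0.0, scale, (d_in, d_out)))
        self.b = Param(np.zeros(d_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = x.astype(np.float32, copy=False)
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x is not None, "backward before forward(train=True)"
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class Conv3dSame(Module):
    """Stride-1, same-padded 3D convolution with an odd cubic kernel.

    Realized in the frequency domain: the cross-correlation of the input
    with the kernel equals a linear convolution with the spatially flipped
    kernel, so forward, input-gradient and weight-gradient are all batched
    rfftn products. For the small volumes and kernel banks used here this
    is far cheaper (in time and memory) than materializing im2col patch
    matrices. The weight is stored as a ``(c_in * k^3, c_out)`` matrix,
    He-initialized; row order is (channel, dz, dy, dx) C-order over the
    kernel cube.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0 or kernel < 3:
            raise ValueError(f"kernel must be odd and >= 3, got {kernel}")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel**3
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    @property
    def n_params(self) -> int:
        return self.w.value.size + self.b.value.size

    def _w_vol(self) -> np.ndarray:
        k = self.kernel
        # (c_in, k, k, k, c_out) -> (c_in, c_out, k, k, k)
        return self.w.value.reshape(self.c_in, k, k, k, self.c_out).transpose(0, 4, 1, 2, 3)

    def _fshape(self, spatial: tuple[int, ...]) -> tuple[int, ...]:
        from scipy.fft import next_fast_len

        return tuple(next_fast_len(n + self.kernel - 1) for n in spatial)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        from scipy import fft as sfft

        x = x.astype(np.float32, copy=False)
        b, c, X, Y, Z = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p = self.kernel // 2
        fs = self._fshape((X, Y, Z))
        axes = (-3, -2, -1)
        xhat = sfft.rfftn(x, s=fs, axes=axes)
        w_flip = self._w_vol()[:, :, ::-1, ::-1, ::-1]
        what_f = sfft.rfftn(np.ascontiguousarray(w_flip), s=fs, axes=axes)
        yhat = np.einsum("bcxyz,coxyz->boxyz", xhat, what_f)
        y = sfft.irfftn(yhat, s=fs, axes=axes)
        y = y[..., p:p + X, p:p + Y, p:p + Z] + self.b.value[None, :, None, None, None]
        if train:
            self._cache = (xhat, (X, Y, Z), fs)
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        from scipy import fft as sfft

        assert self._cache is not None, "backward before forward(train=True)"
        xhat, (X, Y, Z), fs = self._cache
        k, p = self.kernel, self.kernel // 2
        axes = (-3, -2, -1)
        dy = dy.astype(np.float32, copy=False)
        dyhat = sfft.rfftn(dy, s=fs, axes=axes)

        # weight gradient: cross-correlation of x with dy at lags -p..p,
        # i.e. IDFT(Xhat * conj(DYhat))[d] = sum_v dy[v] x[v + d]
        shat = np.einsum("bcxyz,boxyz->coxyz", xhat, np.conj(dyhat))
        s = sfft.irfftn(shat, s=fs, axes=axes)
        lag = [(np.arange(k) - p) % n for n in fs]
        dw_vol = s[:, :, lag[0][:, None, None], lag[1][None, :, None], lag[2][None, None, :]]
        # (c_in, c_out, k, k, k) -> rows (c_in, dz, dy, dx), cols c_out
        self.w.grad += dw_vol.transpose(0, 2, 3, 4, 1).reshape(self.w.value.shape)
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))

        if not need_dx:
            return None
        what = sfft.rfftn(np.ascontiguousarray(self._w_vol()), s=fs, axes=axes)
        dxhat = np.einsum("boxyz,coxyz->bcxyz", dyhat, what)
        dx = sfft.irfftn(dxhat, s=fs, axes=axes)
        return np.ascontiguousarray(
            dx[..., p:p + X, p:p + Y, p:p + Z], dtype=np.float32
        )


class MultiScaleConv3d(Module):
    """Parallel same-padded convolutions at several kernel sizes whose
    outputs are concatenated along the channel axis — the multi-scale
    aggregation of one encoder layer."""

    def __init__(self, c_in: int, c_per_kernel: int, kernels: Sequence[int],
                 rng: np.random.Generator):
        self.branches = [Conv3dSame(c_in, c_per_kernel, k, rng) for k in kernels]
        self.c_out = c_per_kernel * len(self.branches)

    def params(self) -> list[Param]:
        return [p for br in self.branches for p in br.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.concatenate([br.forward(x, train=train) for br in self.branches], axis=1)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        dx = None
        off = 0
        for br in self.branches:
            dslice = dy[:, off:off + br.c_out]
            off += br.c_out
            g = br.backward(np.ascontiguousarray(dslice), need_dx=need_dx)
            if need_dx:
                dx = g if dx is None else dx + g
        return dx


class MaxPool3d(Module):
    def __init__(self, pool: int = 2, stride: int = 2):
        if pool < 1 or stride < 1:
            raise ValueError("pool and stride must be >= 1")
        self.pool, self.stride = pool, stride
        self._cache = None

    def params(self) -> list[Param]:
        return []

    @staticmethod
    def out_dim(n: int, pool: int, stride: int) -> int:
        return (n - pool) // stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p, s = self.pool, self.stride
        for d in x.shape[2:]:
            if self.out_dim(d, p, s) < 1:
                raise ValueError(f"volume too small for pooling: shape {x.shape[2:]}")
        win = sliding_window_view(x, (p, p, p), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        win = np.ascontiguousarray(win).reshape(*win.shape[:5], -1)
        arg = win.argmax(axis=-1)
        out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (x.shape, arg)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        x_shape, arg = self._cache
        p, s = self.pool, self.stride
        b, c, ox, oy, oz = arg.shape
        di, rem = np.divmod(arg, p * p)
        dj, dk = np.divmod(rem, p)
        ix = np.arange(ox)[:, None, None] * s + di
        iy = np.arange(oy)[None, :, None] * s + dj
        iz = np.arange(oz)[None, None, :] * s + dk
        bi = np.arange(b)[:, None, None, None, None]
        ci = np.arange(c)[None, :, None, None, None]
        dx = np.zeros(x_shape, dtype=np.float32)
        np.add.at(dx, (bi, ci, ix, iy, iz), dy)
        return dx


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return dy * self._mask


class LSTM(Module):
    """Single-layer LSTM returning the final hidden state.

    Gate order in the packed weight matrices is (input, forget, cell,
    output); the forget-gate bias is initialized to 1 so early training
    retains memory. ``forward`` consumes ``(B, T, D)`` and returns the
    last hidden state ``(B, H)``; ``backward`` takes the gradient of that
    state and runs truncated-free BPTT over the full window.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(hidden)
        self.d_in, self.hidden = d_in, hidden
        self.wx = Param(rng.uniform(-bound, bound, (d_in, 4 * hidden)))
        self.wh = Param(rng.uniform(-bound, bound, (hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.b = Param(b)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.wx, self.wh, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = x.astype(np.float32, copy=False)
        bsz, T, _ = x.shape
        H = self.hidden
        xf = x.reshape(bsz * T, self.d_in) @ self.wx.value + self.b.value
        xf = xf.reshape(bsz, T, 4 * H)
        h = np.zeros((bsz, H), dtype=np.float32)
        c = np.zeros((bsz, H), dtype=np.float32)
        steps = []
        for t in range(T):
            z = xf[:, t] + h @ self.wh.value
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = sigmoid(z[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            if train:
                steps.append((i, f, g, o, c_prev, h_prev, tc))
        if train:
            self._cache = (x, steps)
        return h

    def backward(self, dh_last: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        x, steps = self._cache
        bsz, T, _ = x.shape
        H = self.hidden
        dxf = np.zeros((bsz, T, 4 * H), dtype=np.float32)
        dh = dh_last.astype(np.float32, copy=False)
        dc = np.zeros_like(dh)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tc = steps[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dxf[:, t] = dz
            self.wh.grad += h_prev.T @ dz
            dh = dz @ self.wh.value.T
            dc = dc * f
        flat = dxf.reshape(bsz * T, 4 * H)
        self.wx.grad += x.reshape(bsz * T, self.d_in).T @ flat
        self.b.grad += flat.sum(axis=0)
        return (flat @ self.wx.value.T).reshape(bsz, T, self.d_in)


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: Iterable[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad * p.grad
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw scores; returns (loss, dlogits)."""
    logits = logits.astype(np.float64, copy=False).ravel()
    y = y.astype(np.float64, copy=False).ravel()
    # log(1 + e^z) computed stably
    loss = np.mean(np.maximum(logits, 0.0) - logits * y + np.log1p(np.exp(-np.abs(logits))))
    p = sigmoid(logits)
    dlogits = ((p - y) / logits.size).astype(np.float32)
    return float(loss), dlogits
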