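"""Minimal NumPy neural-network backend.

Layers store their forward cache and implement an explicit ``backward``;
convolutions are evaluated as a single BLAS GEMM over im2col patch
matrices, which is what makes CPU training of the segmentation network
practical. All tensors are NHWC ``float32``; every layer instance must be
used exactly once per forward pass (caches are overwritten on each call).

Large intermediates (patch matrices, pooling tables, activation outputs)
are written into per-layer buffers that persist across steps: training
repeatedly allocates and frees hundreds of megabytes otherwise, and that
allocator churn progressively degrades long runs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2",
    "Upsample2",
    "Dropout",
    "Adam",
    "he_uniform",
    "sigmoid",
    "maxpool2",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def he_uniform(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator) -> np.ndarray:
    """He/Kaiming uniform initialisation, appropriate for ReLU stacks."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def _buf(store: dict, key: str, shape: tuple[int, ...], dtype=np.float32) -> np.ndarray:
    """Fetch (or grow) a persistent scratch array for ``key``/``shape``."""
    arr = store.get(key)
    if arr is None or arr.shape != shape or arr.dtype != dtype:
        arr = np.empty(shape, dtype)
        store[key] = arr
    return arr


class Conv2d:
    """Same-padding convolution, kernel size 1 or 3, stride 1.

    The forward patch matrix is kept and reused for the weight gradient;
    the input gradient is accumulated by col2im scatter-add, so each
    backward costs two GEMMs and nine slice additions.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k not in (1, 3):
            raise ValueError(f"kernel size {k} unsupported")
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.w = Param(he_uniform((k * k * c_in, c_out), k * k * c_in, rng))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._x: np.ndarray | None = None
        self._cols: np.ndarray | None = None
        self._bufs: dict = {}

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _im2col3(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xp = _buf(self._bufs, "xp", (n, h + 2, w + 2, c), x.dtype)
        xp[:, 0, :, :] = 0.0
        xp[:, h + 1, :, :] = 0.0
        xp[:, :, 0, :] = 0.0
        xp[:, :, w + 1, :] = 0.0
        xp[:, 1:h + 1, 1:w + 1, :] = x
        cols = _buf(self._bufs, "cols", (n * h * w, 9 * c), x.dtype)
        cv = cols.reshape(n, h, w, 9, c)
        k = 0
        for di in range(3):
            for dj in range(3):
                cv[:, :, :, k, :] = xp[:, di:di + h, dj:dj + w, :]
                k += 1
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        dt = np.result_type(x.dtype, self.w.value.dtype)
        y = _buf(self._bufs, "y", (n * h * w, self.c_out), dt)
        if self.k == 1:
            self._x = x
            np.matmul(x.reshape(-1, self.c_in), self.w.value, out=y)
        else:
            self._cols = self._im2col3(x)
            np.matmul(self._cols, self.w.value, out=y)
        y += self.b.value
        return y.reshape(n, h, w, self.c_out)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, _ = gy.shape
        gym = np.ascontiguousarray(gy).reshape(-1, self.c_out)
        gt = np.result_type(gym.dtype, self.w.value.dtype)
        self.b.grad += gym.sum(axis=0)
        dw = _buf(self._bufs, "dw", self.w.value.shape, gt)
        if self.k == 1:
            np.matmul(self._x.reshape(-1, self.c_in).T, gym, out=dw)
            self.w.grad += dw
            gx = _buf(self._bufs, "gx", (n * h * w, self.c_in), gt)
            np.matmul(gym, self.w.value.T, out=gx)
            return gx.reshape(n, h, w, self.c_in)
        np.matmul(self._cols.T, gym, out=dw)
        self.w.grad += dw
        gcols = _buf(self._bufs, "gcols", (n * h * w, 9 * self.c_in), gt)
        np.matmul(gym, self.w.value.T, out=gcols)
        gv = gcols.reshape(n, h, w, 9, self.c_in)
        gxp = _buf(self._bufs, "gxp", (n, h + 2, w + 2, self.c_in), gt)
        gxp.fill(0.0)
        k = 0
        for di in range(3):
            for dj in range(3):
                gxp[:, di:di + h, dj:dj + w, :] += gv[:, :, :, k, :]
                k += 1
        gx = _buf(self._bufs, "gx3", (n, h, w, self.c_in), gt)
        gx[...] = gxp[:, 1:h + 1, 1:w + 1, :]
        return gx


class ReLU:
    def __init__(self):
        self._bufs: dict = {}

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        m = _buf(self._bufs, "m", x.shape, bool)
        np.greater(x, 0, out=m)
        y = _buf(self._bufs, "y", x.shape, x.dtype)
        np.multiply(x, m, out=y)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = _buf(self._bufs, "g", gy.shape, gy.dtype)
        np.multiply(gy, self._bufs["m"], out=g)
        return g


class Sigmoid:
    def __init__(self):
        self._y: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = sigmoid(x)
        return self._y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        y = self._y
        return gy * y * (1.0 - y)


def maxpool2(x: np.ndarray) -> np.ndarray:
    """Stateless 2x2 stride-2 max pool over (N,H,W,C) or (H,W)."""
    if x.ndim == 2:
        h, w = x.shape
        return x.reshape(h // 2, 2, w // 2, 2).max(axis=(1, 3))
    n, h, w, c = x.shape
    return x.reshape(n, h // 2, 2, w // 2, 2, c).max(axis=(2, 4))


class MaxPool2:
    """2x2 stride-2 max pool; gradient routed to the first argmax on ties."""

    def __init__(self):
        self._bufs: dict = {}
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._shape = x.shape
        xr = _buf(self._bufs, "xr", (n, h // 2, w // 2, c, 4), x.dtype)
        xr[..., 0] = x[:, 0::2, 0::2, :]
        xr[..., 1] = x[:, 0::2, 1::2, :]
        xr[..., 2] = x[:, 1::2, 0::2, :]
        xr[..., 3] = x[:, 1::2, 1::2, :]
        idx = _buf(self._bufs, "idx", (n, h // 2, w // 2, c), np.int64)
        np.argmax(xr, axis=-1, out=idx)
        y = _buf(self._bufs, "y", (n, h // 2, w // 2, c), x.dtype)
        np.max(xr, axis=-1, out=y)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        gr = _buf(self._bufs, "gr", (n, h // 2, w // 2, c, 4), gy.dtype)
        gr.fill(0.0)
        np.put_along_axis(gr, self._bufs["idx"][..., None], gy[..., None],
                          axis=-1)
        gx = _buf(self._bufs, "gx", (n, h, w, c), gy.dtype)
        gx[:, 0::2, 0::2, :] = gr[..., 0]
        gx[:, 0::2, 1::2, :] = gr[..., 1]
        gx[:, 1::2, 0::2, :] = gr[..., 2]
        gx[:, 1::2, 1::2, :] = gr[..., 3]
        return gx


class Upsample2:
    """Nearest-neighbour x2 upsampling."""

    def __init__(self):
        self._bufs: dict = {}

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        y = _buf(self._bufs, "y", (n, 2 * h, 2 * w, c), x.dtype)
        y[:, 0::2, 0::2, :] = x
        y[:, 0::2, 1::2, :] = x
        y[:, 1::2, 0::2, :] = x
        y[:, 1::2, 1::2, :] = x
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h2, w2, c = gy.shape
        gx = _buf(self._bufs, "gx", (n, h2 // 2, w2 // 2, c), gy.dtype)
        gx[...] = gy[:, 0::2, 0::2, :]
        gx += gy[:, 0::2, 1::2, :]
        gx += gy[:, 1::2, 0::2, :]
        gx += gy[:, 1::2, 1::2, :]
        return gx


class Dropout:
    """Inverted dropout; inert at rate 0 (the default training setting)."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = float(rate)
        self._rng = rng
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        return gy * self._mask


class Adam:
    """Adam optimiser over a flat parameter list (fully in-place updates)."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._s1 = [np.empty_like(p.value) for p in params]
        self._s2 = [np.empty_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v, s1, s2 in zip(self.params, self._m, self._v,
                                   self._s1, self._s2):
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            np.divide(m, b1t, out=s1)
            np.divide(v, b2t, out=s2)
            np.sqrt(s2, out=s2)
            s2 += self.eps
            s1 /= s2
            s1 *= self.lr
            p.value -= s1
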