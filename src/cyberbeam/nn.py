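"""A small CPU neural-network engine (numpy, explicit backprop).

Implements exactly the pieces the dense 3-D U-Net needs -- 3-D
convolution (same padding), batch normalization, ReLU, 2x2x2 max pooling,
2x2x2 stride-2 transposed convolution and an Adam optimizer -- as layer
objects with ``forward``/``backward`` methods and explicit parameter
lists.  Tensors are ``float32`` in channels-last layout
``(N, X, Y, Z, C)``: convolutions then reduce to one small GEMM per
kernel offset on contiguous memory, which is what keeps a pure-numpy
training step fast on a single core.

The engine is deterministic: all initialization flows from a
caller-supplied generator and every operation is a plain numpy
expression, so repeated runs with the same seed reproduce training
bit-for-bit on the same BLAS.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "Param",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool2",
    "Deconv2",
    "Adam",
]

_DT = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(_DT)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


def _conv_raw(x: np.ndarray, w: np.ndarray, b: Optional[np.ndarray]) -> np.ndarray:
    """Stride-1 same-padding correlation.

    ``w`` has shape ``(k^3, Cin, Cout)`` (kernel offsets flattened in
    C order).  Accumulates one ``(M, Cin) @ (Cin, Cout)`` product per
    offset over views of the padded input.
    """
    n, xx, yy, zz, c = x.shape
    k3, _, cout = w.shape
    k = round(k3 ** (1 / 3))
    if k == 1:
        out = x.reshape(-1, c) @ w[0]
    else:
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        m = n * xx * yy * zz
        out = np.zeros((m, cout), dtype=_DT)
        i = 0
        for a in range(k):
            for bb in range(k):
                for cc in range(k):
                    v = xp[:, a:a + xx, bb:bb + yy, cc:cc + zz, :].reshape(m, c)
                    out += v @ w[i]
                    i += 1
    if b is not None:
        out += b
    return out.reshape(n, xx, yy, zz, cout)


class Conv3d:
    """k x k x k convolution (k = 1 or 3), stride 1, zero ('same') padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k**3
        scale = np.sqrt(2.0 / fan_in)  # He init for the ReLU-heavy net
        self.k = k
        self.w = Param(rng.normal(0.0, scale, (k**3, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._x: Optional[np.ndarray] = None

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return _conv_raw(x, self.w.value, self.b.value)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None, "backward before forward"
        n, xx, yy, zz, c = x.shape
        cout = self.w.value.shape[2]
        m = n * xx * yy * zz
        gmat = gout.reshape(m, cout)
        k = self.k
        self.b.grad += gmat.sum(axis=0)
        if k == 1:
            self.w.grad[0] += x.reshape(m, c).T @ gmat
            gx = (gmat @ self.w.value[0].T).reshape(x.shape)
        else:
            p = k // 2
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
            i = 0
            for a in range(k):
                for bb in range(k):
                    for cc in range(k):
                        v = xp[:, a:a + xx, bb:bb + yy, cc:cc + zz, :].reshape(m, c)
                        self.w.grad[i] += v.T @ gmat
                        i += 1
            # input gradient = correlation with flipped, transposed kernels
            wflip = self.w.value[::-1].transpose(0, 2, 1)
            gx = _conv_raw(gout, np.ascontiguousarray(wflip), None)
        self._x = None
        return gx


class BatchNorm3d:
    """Per-channel batch normalization over (N, X, Y, Z)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=_DT)
        self.running_var = np.ones(c, dtype=_DT)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0, 1, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean + (1 - self.momentum) * mean).astype(_DT)
            self.running_var = (self.momentum * self.running_var + (1 - self.momentum) * var).astype(_DT)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(_DT)
        xhat = (x - mean) * invstd
        if train:
            self._cache = (xhat, invstd, x.shape)
        return (self.gamma.value * xhat + self.beta.value).astype(_DT)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, invstd, shape = self._cache
        axes = (0, 1, 2, 3)
        m = shape[0] * shape[1] * shape[2] * shape[3]
        self.gamma.grad += (gout * xhat).sum(axis=axes)
        self.beta.grad += gout.sum(axis=axes)
        g = gout * self.gamma.value
        gsum = g.sum(axis=axes)
        gxsum = (g * xhat).sum(axis=axes)
        gx = (g - gsum / m - xhat * (gxsum / m)) * invstd
        self._cache = None
        return gx.astype(_DT)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gx = gout * self._mask
        self._mask = None
        return gx


class MaxPool2:
    """2x2x2 max pooling; spatial dims must be even."""

    def __init__(self):
        self._cache = None

    def params(self) -> List[Param]:
        return []

    @staticmethod
    def _windows(x: np.ndarray) -> np.ndarray:
        n, xx, yy, zz, c = x.shape
        return (x.reshape(n, xx // 2, 2, yy // 2, 2, zz // 2, 2, c)
                 .transpose(0, 1, 3, 5, 2, 4, 6, 7)
                 .reshape(n, xx // 2, yy // 2, zz // 2, 8, c))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        xr = self._windows(x)
        idx = xr.argmax(axis=4)
        out = np.take_along_axis(xr, idx[:, :, :, :, None], axis=4)[:, :, :, :, 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        n, xx, yy, zz, c = shape
        g8 = np.zeros((n, xx // 2, yy // 2, zz // 2, 8, c), dtype=_DT)
        np.put_along_axis(g8, idx[:, :, :, :, None], gout[:, :, :, :, None], axis=4)
        gx = (g8.reshape(n, xx // 2, yy // 2, zz // 2, 2, 2, 2, c)
                .transpose(0, 1, 4, 2, 5, 3, 6, 7)
                .reshape(shape))
        self._cache = None
        return gx


class Deconv2:
    """2x2x2 transposed convolution with stride 2 (doubles each spatial dim)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.w = Param(rng.normal(0.0, scale, (c_in, c_out * 8)))
        self.b = Param(np.zeros(c_out))
        self.c_out = c_out
        self._x = None

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, xx, yy, zz, c = x.shape
        if train:
            self._x = x
        out8 = (x.reshape(-1, c) @ self.w.value).reshape(n, xx, yy, zz, 2, 2, 2, self.c_out)
        out = (out8.transpose(0, 1, 4, 2, 5, 3, 6, 7)
                   .reshape(n, 2 * xx, 2 * yy, 2 * zz, self.c_out))
        return out + self.b.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._x
        n, xx, yy, zz, c = x.shape
        g8 = (gout.reshape(n, xx, 2, yy, 2, zz, 2, self.c_out)
                  .transpose(0, 1, 3, 5, 2, 4, 6, 7)
                  .reshape(-1, self.c_out * 8))
        xmat = x.reshape(-1, c)
        self.w.grad += xmat.T @ g8
        self.b.grad += gout.sum(axis=(0, 1, 2, 3))
        gx = (g8 @ self.w.value.T).reshape(x.shape)
        self._x = None
        return gx.astype(_DT)


class Adam:
    """Adam with externally scheduled learning rate."""

    def __init__(self, params: Sequence[Param], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)).astype(_DT)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
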