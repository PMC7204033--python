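"""Minimal 2D CNN layer library: explicit forward and backward passes.

Layers operate on NHWC float arrays (channels last), which keeps every hot
path — convolution, batch normalization, concatenation — contiguous and
BLAS-bound on a CPU.  A 3×3 convolution is evaluated as nine shifted GEMMs
over the padded input rather than through an im2col buffer, so no large
strided copies are made.  Parameter gradients accumulate on :class:`Param`
objects and are consumed by :class:`Adam`; all gradients are verified
against finite differences in the test suite.

The public network API (:mod:`cavseg.nn.model`) still speaks NCHW, the
field's convention; the transpose happens once at the network boundary.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Dropout",
    "MaxPool2",
    "BilinearResize",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)


class Module:
    """Base class: parameter/buffer traversal with hierarchical names."""

    def _params(self) -> dict[str, Param]:
        return {}

    def _buffers(self) -> dict[str, np.ndarray]:
        return {}

    def _children(self) -> dict[str, "Module"]:
        return {}

    def named_params(self, prefix: str = "") -> Iterator[tuple[str, Param]]:
        for name, p in self._params().items():
            yield prefix + name, p
        for cname, child in self._children().items():
            yield from child.named_params(prefix + cname + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers().items():
            yield prefix + name, b
        for cname, child in self._children().items():
            yield from child.named_buffers(prefix + cname + ".")

    def set_buffer(self, name: str, value: np.ndarray) -> None:
        head, _, rest = name.partition(".")
        if rest:
            self._children()[head].set_buffer(rest, value)
        else:
            np.copyto(self._buffers()[name], value)

    def num_parameters(self) -> int:
        return sum(p.data.size for _, p in self.named_params())


class Conv2d(Module):
    """2D convolution ('same' padding for odd kernels, stride 1), NHWC.

    Weights are stored as (k, k, Cin, Cout) so each kernel offset (i, j)
    contributes one contiguous (N·Hp·Wp, Cin) @ (Cin, Cout) GEMM.
    """

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.cin, self.cout, self.kernel = cin, cout, kernel
        self.pad = kernel // 2
        scale = np.sqrt(2.0 / (cin * kernel * kernel))  # He init for ReLU nets
        self.W = Param((rng.standard_normal((kernel, kernel, cin, cout)) * scale).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self._xp: np.ndarray | None = None

    def _params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if x.shape[-1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[-1]}")
        n, h, w, _ = x.shape
        k, p = self.kernel, self.pad
        if k == 1:
            self._xp = x
            out = x.reshape(-1, self.cin) @ self.W.data[0, 0] + self.b.data
            return out.reshape(n, h, w, self.cout)
        xp = np.zeros((n, h + 2 * p, w + 2 * p, self.cin), dtype=x.dtype)
        xp[:, p:p + h, p:p + w, :] = x
        self._xp = xp
        hp, wp = xp.shape[1], xp.shape[2]
        flat = xp.reshape(-1, self.cin)
        y = np.empty((n, h, w, self.cout), dtype=x.dtype)
        y[:] = self.b.data
        for i in range(k):
            for j in range(k):
                z = (flat @ self.W.data[i, j]).reshape(n, hp, wp, self.cout)
                y += z[:, i:i + h, j:j + w, :]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        self._xp = None
        k, p = self.kernel, self.pad
        self.b.grad += dy.sum(axis=(0, 1, 2))
        if k == 1:
            flat = xp.reshape(-1, self.cin)
            dyflat = dy.reshape(-1, self.cout)
            self.W.grad[0, 0] += flat.T @ dyflat
            return (dyflat @ self.W.data[0, 0].T).reshape(xp.shape)
        n, hp, wp, _ = xp.shape
        h, w = hp - 2 * p, wp - 2 * p
        xpflat = xp.reshape(-1, self.cin)
        dyp = np.zeros((n, hp, wp, self.cout), dtype=dy.dtype)
        dypflat = dyp.reshape(-1, self.cout)
        for i in range(k):
            for j in range(k):
                dyp[:, i:i + h, j:j + w, :] = dy
                self.W.grad[i, j] += xpflat.T @ dypflat
                dyp[:, i:i + h, j:j + w, :] = 0.0
        # input gradient = 'same' convolution of dy with the spatially
        # flipped, transposed kernels
        dyp[:, p:p + h, p:p + w, :] = dy
        flat = dypflat
        dx = np.zeros((n, h, w, self.cin), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                wt = self.W.data[k - 1 - i, k - 1 - j].T
                z = (flat @ wt).reshape(n, hp, wp, self.cin)
                dx += z[:, i:i + h, j:j + w, :]
        return dx


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) with running statistics (NHWC)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def _params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, training=False, rng=None):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean.astype(x.dtype)) * inv
        self._cache = (xhat, inv, training)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, dy):
        xhat, inv, training = self._cache
        self._cache = None
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        if not training:
            return dy * (self.gamma.data * inv)
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        dxhat = dy * self.gamma.data
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        return (inv / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Module):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        out = dy * self._mask
        self._mask = None
        return out


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = rng.random(x.shape, dtype=np.float32) >= self.p
        self._mask = keep.astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        out = dy * self._mask
        self._mask = None
        return out


class MaxPool2(Module):
    """2×2 max pooling with floor semantics (odd trailing rows are dropped)."""

    def forward(self, x, training=False, rng=None):
        n, h, w, c = x.shape
        hh, wh = h // 2, w // 2
        xc = x[:, : 2 * hh, : 2 * wh, :].reshape(n, hh, 2, wh, 2, c)
        patches = xc.transpose(0, 1, 3, 2, 4, 5).reshape(n, hh, wh, 4, c)
        idx = patches.argmax(axis=3)
        self._cache = (x.shape, idx)
        return np.take_along_axis(patches, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy):
        xshape, idx = self._cache
        self._cache = None
        n, h, w, c = xshape
        hh, wh = h // 2, w // 2
        dpatches = np.zeros((n, hh, wh, 4, c), dtype=dy.dtype)
        np.put_along_axis(dpatches, idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dxc = dpatches.reshape(n, hh, wh, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros(xshape, dtype=dy.dtype)
        dx[:, : 2 * hh, : 2 * wh, :] = dxc.reshape(n, 2 * hh, 2 * wh, c)
        return dx


class BilinearResize(Module):
    """Bilinear interpolation to an arbitrary target size (half-pixel centers).

    Forward is the separable linear map ``A_h @ x @ A_w^T``; backward is its
    exact transpose, so odd encoder sizes are restored losslessly.
    """

    _matrix_cache: dict[tuple[int, int, str], np.ndarray] = {}

    @classmethod
    def _matrix(cls, src: int, dst: int, dtype) -> np.ndarray:
        key = (src, dst, np.dtype(dtype).str)
        if key not in cls._matrix_cache:
            a = np.zeros((dst, src), dtype=np.float64)
            pos = np.clip((np.arange(dst) + 0.5) * src / dst - 0.5, 0, src - 1)
            i0 = np.floor(pos).astype(int)
            i1 = np.minimum(i0 + 1, src - 1)
            w1 = pos - i0
            np.add.at(a, (np.arange(dst), i0), 1.0 - w1)
            np.add.at(a, (np.arange(dst), i1), w1)
            cls._matrix_cache[key] = a.astype(dtype)
        return cls._matrix_cache[key]

    @staticmethod
    def _apply(x: np.ndarray, ah: np.ndarray, aw: np.ndarray) -> np.ndarray:
        t = np.tensordot(ah, x, axes=([1], [1]))          # (th, N, W, C)
        y = np.tensordot(aw, t, axes=([1], [2]))          # (tw, th, N, C)
        return np.ascontiguousarray(y.transpose(2, 1, 0, 3))

    def forward(self, x, target: tuple[int, int], training=False, rng=None):
        th, tw = target
        ah = self._matrix(x.shape[1], th, x.dtype)
        aw = self._matrix(x.shape[2], tw, x.dtype)
        self._cache = (ah, aw)
        return self._apply(x, ah, aw)

    def backward(self, dy):
        ah, aw = self._cache
        self._cache = None
        return self._apply(dy, np.ascontiguousarray(ah.T), np.ascontiguousarray(aw.T))


class Adam:
    """Adaptive-moment optimizer (standard published defaults, β=(0.9, 0.999))."""

    def __init__(self, params: list[Param], lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad.fill(0.0)

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray, axis: int) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean pixel-wise cross-entropy and its gradient w.r.t. the logits.

    ``logits``: (N, K, H, W); ``targets``: (N, H, W) integer class labels.
    """
    k = logits.shape[1]
    probs = softmax(logits, axis=1)
    flat = np.ascontiguousarray(probs.transpose(0, 2, 3, 1)).reshape(-1, k)
    t = targets.reshape(-1).astype(int)
    rows = np.arange(flat.shape[0])
    picked = flat[rows, t]
    loss = float(-np.log(np.maximum(picked, 1e-12)).mean())
    dflat = flat
    dflat[rows, t] -= 1.0
    dflat /= flat.shape[0]
    dlogits = dflat.reshape(logits.shape[0], logits.shape[2], logits.shape[3], k)
    return loss, np.ascontiguousarray(dlogits.transpose(0, 3, 1, 2))
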