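"""Minimal CPU deep-learning engine used by the hologram classifiers.

Layers operate on float32 arrays in channels-last layout — ``(B, D, H, W, C)``
for volumetric data and ``(B, H, W, C)`` for planar data — so that the inner
GEMM of each convolution runs over contiguous memory.  Every layer implements
``forward(x, train)`` and ``backward(grad)``; parameters carry their gradient
and are updated by :class:`Adam`.

Convolutions are stride-1 with "same" zero padding and are evaluated as an
im2col gather followed by a single BLAS matmul; the gathered patch matrix is
cached in the forward pass and reused for the weight gradient.

Only what the classifiers need is implemented; this is not a general autograd.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Sequential",
    "Conv",
    "BatchNorm",
    "LeakyReLU",
    "SpatialMaxPool",
    "DepthMaxPool",
    "SpatialAvgPool",
    "Flatten",
    "Dropout",
    "Linear",
    "LogSoftmax",
    "Adam",
    "set_default_dtype",
]

_default_dtype = np.float32


def set_default_dtype(dtype) -> None:
    """Set the working float dtype (float32 default; float64 for gradient checks)."""
    global _default_dtype
    _default_dtype = np.dtype(dtype).type


def _dt():
    return _default_dtype


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data, dtype=_dt())
        self.grad = np.zeros_like(self.data)
        self.name = name


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _kernel_offsets(kernel: tuple[int, ...]):
    grids = np.meshgrid(*[np.arange(k) for k in kernel], indexing="ij")
    return list(zip(*[g.ravel() for g in grids]))


class Conv(Layer):
    """Stride-1 same-padding N-D convolution (N = 2 or 3 spatial axes).

    ``kernel`` is ``(kd, kh, kw)`` for volumes or ``(kh, kw)`` for planes; a
    kernel of all ones implements the 1x1(x1) projection used by the residual
    skip branches.  He-normal initialisation.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, ...], rng: np.random.Generator, name: str = "conv") -> None:
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, tuple(kernel)
        if any(k % 2 == 0 for k in self.kernel):
            raise ValueError("only odd kernel sizes are supported (same padding)")
        fan_in = in_ch * int(np.prod(self.kernel))
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.weight = Parameter(w, f"{name}.weight")
        self.bias = Parameter(np.zeros(out_ch), f"{name}.bias")
        self._offsets = _kernel_offsets(self.kernel)
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def _slices(self, spatial: tuple[int, ...]):
        for off in self._offsets:
            yield (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial)) + (slice(None),)

    def forward(self, x, train=False):
        # The kernel sum is evaluated offset by offset: each shifted window of
        # the padded input is flattened to (N, C_in) and hit with the matching
        # (C_in, C_out) weight slab, accumulating into one output buffer.  All
        # copies are contiguous; in training mode the materialised windows are
        # kept for the weight-gradient GEMMs.
        x = np.ascontiguousarray(x, dtype=_dt())
        pads = [(0, 0)] + [(k // 2, k // 2) for k in self.kernel] + [(0, 0)]
        xp = np.pad(x, pads)
        spatial = x.shape[1:-1]
        n = x.size // self.in_ch
        w3 = self.weight.data.reshape(self.out_ch, len(self._offsets), self.in_ch)
        out = np.empty((n, self.out_ch), dtype=_dt())
        out[:] = self.bias.data
        tmp = np.empty((n, self.out_ch), dtype=_dt())
        windows = [] if train else None
        for j, sl in enumerate(self._slices(spatial)):
            xs = xp[sl].reshape(n, self.in_ch)
            np.matmul(xs, w3[:, j, :].T, out=tmp)
            out += tmp
            if train:
                windows.append(xs)
        self._cache = (windows, x.shape) if train else None
        return out.reshape(x.shape[:-1] + (self.out_ch,))

    def backward(self, grad):
        windows, x_shape = self._cache
        spatial = x_shape[1:-1]
        n = int(np.prod(x_shape[:-1]))
        g2 = np.ascontiguousarray(grad, dtype=_dt()).reshape(n, self.out_ch)
        self.bias.grad += g2.sum(axis=0)
        w3 = self.weight.data.reshape(self.out_ch, len(self._offsets), self.in_ch)
        gw3 = self.weight.grad.reshape(self.out_ch, len(self._offsets), self.in_ch)
        for j, xs in enumerate(windows):
            gw3[:, j, :] += g2.T @ xs
        # dL/dx is the same-padding convolution of the gradient with the
        # spatially flipped kernel, so it reuses the forward accumulation
        # pattern instead of scatter-adds.
        pads = [(0, 0)] + [(k // 2, k // 2) for k in self.kernel] + [(0, 0)]
        gp = np.pad(g2.reshape(x_shape[:-1] + (self.out_ch,)), pads)
        dx = np.zeros((n, self.in_ch), dtype=_dt())
        tmp = np.empty((n, self.in_ch), dtype=_dt())
        n_off = len(self._offsets)
        for j, sl in enumerate(self._slices(spatial)):
            gs = gp[sl].reshape(n, self.out_ch)
            np.matmul(gs, w3[:, n_off - 1 - j, :], out=tmp)
            dx += tmp
        self._cache = None
        return dx.reshape(x_shape)


class BatchNorm(Layer):
    """Per-channel batch normalisation over all leading axes (channels-last)."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn") -> None:
        self.gamma = Parameter(np.ones(n_ch), f"{name}.gamma")
        self.beta = Parameter(np.zeros(n_ch), f"{name}.beta")
        self.running_mean = np.zeros(n_ch, dtype=_dt())
        self.running_var = np.ones(n_ch, dtype=_dt())
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=_dt())
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // x.shape[-1]
            self.running_mean += self.momentum * (mean - self.running_mean)
            unbiased = var * n / max(n - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        if train:
            self._cache = (xhat, invstd, axes)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, grad):
        xhat, invstd, axes = self._cache
        n = grad.size // grad.shape[-1]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.data
        dx = invstd * (g - g.mean(axis=axes) - xhat * (g * xhat).mean(axis=axes))
        self._cache = None
        return dx.astype(_dt())


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01) -> None:
        self.slope = slope
        self._mask = None

    def forward(self, x, train=False):
        mask = x < 0
        out = np.where(mask, self.slope * x, x)
        if train:
            self._mask = mask
        return out.astype(_dt())

    def backward(self, grad):
        grad = np.where(self._mask, self.slope * grad, grad)
        self._mask = None
        return grad.astype(_dt())


class SpatialMaxPool(Layer):
    """2x2 max pool over the H and W axes; leaves any depth axis untouched.

    Ties split the gradient evenly between tied positions (measure-zero event
    for real-valued activations).
    """

    def __init__(self) -> None:
        self._cache = None

    def forward(self, x, train=False):
        *lead, h, w, c = x.shape
        xr = x.reshape(*lead, h // 2, 2, w // 2, 2, c)
        m = xr.max(axis=(-4, -2))
        if train:
            self._cache = (xr, m)
        return np.ascontiguousarray(m)

    def backward(self, grad):
        xr, m = self._cache
        mask = (xr == m[..., :, None, :, None, :]).astype(_dt())
        counts = mask.sum(axis=(-4, -2))
        g = (grad / counts)[..., :, None, :, None, :] * mask
        *lead, h2, _, w2, _, c = xr.shape
        self._cache = None
        return g.reshape(*lead, h2 * 2, w2 * 2, c)


class DepthMaxPool(Layer):
    """Global max pool over the depth axis: (B, D, H, W, C) -> (B, H, W, C)."""

    def __init__(self) -> None:
        self._cache = None

    def forward(self, x, train=False):
        m = x.max(axis=1)
        if train:
            self._cache = (x, m)
        return np.ascontiguousarray(m)

    def backward(self, grad):
        x, m = self._cache
        mask = (x == m[:, None]).astype(_dt())
        counts = mask.sum(axis=1)
        g = mask * (grad / counts)[:, None]
        self._cache = None
        return g


class SpatialAvgPool(Layer):
    """Average pool (B, H, W, C) down to (B, out, out, C) with equal blocks."""

    def __init__(self, out_size: int = 2) -> None:
        self.out_size = out_size
        self._block = None

    def forward(self, x, train=False):
        b, h, w, c = x.shape
        if h % self.out_size or w % self.out_size:
            raise ValueError(f"spatial size {h}x{w} not divisible by {self.out_size}")
        self._block = (h // self.out_size, w // self.out_size)
        xr = x.reshape(b, self.out_size, self._block[0], self.out_size, self._block[1], c)
        return np.ascontiguousarray(xr.mean(axis=(2, 4)))

    def backward(self, grad):
        bh, bw = self._block
        b, o, _, c = grad.shape
        g = grad[:, :, None, :, None, :] / (bh * bw)
        return np.broadcast_to(g, (b, o, bh, o, bw, c)).reshape(b, o * bh, o * bw, c).astype(_dt())


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        if not 0 <= p < 1:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p, self.rng = p, rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(_dt()) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        g = grad * self._mask
        self._mask = None
        return g


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator, name: str = "linear") -> None:
        w = rng.normal(0.0, np.sqrt(2.0 / in_f), size=(out_f, in_f))
        self.weight = Parameter(w, f"{name}.weight")
        self.bias = Parameter(np.zeros(out_f), f"{name}.bias")
        self._x = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=_dt())
        if train:
            self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad):
        grad = np.ascontiguousarray(grad, dtype=_dt())
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        self._x = None
        return grad @ self.weight.data


class LogSoftmax(Layer):
    """Row-wise log-softmax: l_c = z_c - log sum_i exp(z_i)."""

    def __init__(self) -> None:
        self._out = None

    def forward(self, x, train=False):
        z = x - x.max(axis=1, keepdims=True)
        out = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        if train:
            self._out = out
        return out.astype(_dt())

    def backward(self, grad):
        softmax = np.exp(self._out)
        self._out = None
        return (grad - softmax * grad.sum(axis=1, keepdims=True)).astype(_dt())


class Adam:
    """Adam optimiser; ``weight_decay`` is added to the raw gradient (L2 style)."""

    def __init__(self, params: list[Parameter], lr: float = 2e-4, betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0) -> None:
        self.params = params
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
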