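"""Minimal NumPy neural-network engine used by the segmentation networks.

Implements exactly the layer set the encoder--decoder architectures need:
same-padded (grouped) 2-D convolution, 2x2 stride-2 transposed convolution,
batch normalization, ReLU, 2x2 max pooling -- each with a hand-written
backward pass -- plus the Adam optimizer.  All arithmetic is float32 and
fully deterministic for a fixed seed.

Layers follow a caching convention: ``forward(x, training)`` stores whatever
the matching ``backward(grad)`` needs; ``backward`` returns the gradient
with respect to the layer input and accumulates parameter gradients in
``Param.grad``.  Tensors are NCHW.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A trainable array with its gradient buffer."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base class; stateless layers only override forward/backward."""

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _windows(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """Same-padded sliding k x k windows: (N, C, H, W, k, k) view."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    return sliding_window_view(x, (k, k), axis=(2, 3))


class Conv2d(Layer):
    """Same-padded grouped convolution with odd square kernels.

    Weight layout is (groups, out_per_group, in_per_group, k, k), matching the
    grouped-convolution definition: input and output channels are partitioned
    into ``groups`` independent blocks, dividing weights and MACs by the group
    count.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 groups: int = 1, bias: bool = True, *, rng: np.random.Generator,
                 name: str = "conv"):
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd and >= 1, got {kernel_size}")
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"groups={groups} must divide in_channels={in_channels} "
                f"and out_channels={out_channels}")
        self.cin, self.cout, self.k, self.groups = in_channels, out_channels, kernel_size, groups
        self.pad = (kernel_size - 1) // 2
        cg = in_channels // groups
        fan_in = cg * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(groups, out_channels // groups, cg, kernel_size, kernel_size))
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(out_channels)) if bias else None
        self._x_shape = None
        self._cols = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        g = self.groups
        win = _windows(x, self.k, self.pad)                # (N, C, H, W, k, k)
        win = win.reshape(n, g, c // g, h, w, self.k, self.k)
        y = np.einsum("ngchwij,gocij->ngohw", win, self.weight.data,
                      optimize=True).reshape(n, self.cout, h, w)
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        if training:
            self._x_shape = x.shape
            self._cols = win
        return np.ascontiguousarray(y)  # dtype follows the input's

    def backward(self, grad):
        n, _, h, w = grad.shape
        g = self.groups
        gy = grad.reshape(n, g, self.cout // g, h, w)
        self.weight.grad += np.einsum("ngohw,ngchwij->gocij", gy, self._cols, optimize=True)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        # grad wrt input: same-padded correlation of grad with the flipped kernel,
        # summed over output channels within each group.
        w_flip = self.weight.data[..., ::-1, ::-1]
        gwin = _windows(grad, self.k, self.pad).reshape(
            n, g, self.cout // g, h, w, self.k, self.k)
        gx = np.einsum("ngohwij,gocij->ngchw", gwin, w_flip, optimize=True)
        self._cols = None
        return np.ascontiguousarray(gx.reshape(self._x_shape), dtype=DTYPE)


class ConvTranspose2d(Layer):
    """2x2 stride-2 transposed convolution ("up-convolution").

    Doubles the spatial size; each input pixel paints one disjoint 2x2 output
    block, so the operation performs exactly 4*Cin*Cout MACs per input pixel.
    """

    K = 2

    def __init__(self, in_channels: int, out_channels: int, *,
                 rng: np.random.Generator, name: str = "up"):
        self.cin, self.cout = in_channels, out_channels
        fan_in = in_channels * self.K * self.K
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(in_channels, out_channels, self.K, self.K))
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(out_channels))
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        y = np.einsum("nchw,coij->nohiwj", x, self.weight.data, optimize=True)
        y = y.reshape(n, self.cout, 2 * h, 2 * w) + self.bias.data[None, :, None, None]
        if training:
            self._x = x
        return np.ascontiguousarray(y, dtype=DTYPE)

    def backward(self, grad):
        n, _, h2, w2 = grad.shape
        g = grad.reshape(n, self.cout, h2 // 2, 2, w2 // 2, 2)
        self.weight.grad += np.einsum("nohiwj,nchw->coij", g, self._x, optimize=True)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        gx = np.einsum("nohiwj,coij->nchw", g, self.weight.data, optimize=True)
        self._x = None
        return np.ascontiguousarray(gx, dtype=DTYPE)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 *, name: str = "bn"):
        self.c = channels
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(f"{name}.weight", np.ones(channels))
        self.beta = Param(f"{name}.bias", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        y = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        if training:
            self._cache = (xhat, inv)
        return np.ascontiguousarray(y, dtype=DTYPE)

    def backward(self, grad):
        xhat, inv = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gxhat = grad * self.gamma.data[None, :, None, None]
        gx = (inv[None, :, None, None] / m) * (
            m * gxhat
            - gxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True))
        self._cache = None
        return np.ascontiguousarray(gx, dtype=DTYPE)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False):
        y = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, grad):
        gx = grad * self._mask
        self._mask = None
        return gx


class MaxPool2d(Layer):
    """2x2 stride-2 max pooling; ties resolve to the first element."""

    def __init__(self):
        self._argmax = None
        self._shape = None

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max pooling needs even spatial dims, got {h}x{w}")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, 4)
        if training:
            self._argmax = flat.argmax(axis=-1)
            self._shape = x.shape
        return np.ascontiguousarray(flat.max(axis=-1), dtype=DTYPE)

    def backward(self, grad):
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        gx = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._argmax = None
        return np.ascontiguousarray(gx.reshape(n, c, h, w), dtype=DTYPE)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def buffers(self):
        out = {}
        for i, l in enumerate(self.layers):
            for k, v in l.buffers().items():
                out[f"{i}.{k}"] = v
        return out

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-pixel binary cross-entropy from logits.

    Returns ``(loss, dloss/dz)``.  Uses log(1+exp(-|z|)) for stability;
    at z == 0 the loss is ln 2 regardless of the target.
    """
    z = z.astype(np.float64)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - t) / z.size
    return float(loss.mean()), grad.astype(DTYPE)


def soft_dice_loss(z: np.ndarray, t: np.ndarray, eps: float = 1.0) -> tuple[float, np.ndarray]:
    """1 - soft Dice on sigmoid probabilities, with gradient wrt logits."""
    p = sigmoid(z)
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum()) + eps
    dice = (2.0 * inter + eps) / denom
    # d dice / d p
    ddp = (2.0 * t * denom - (2.0 * inter + eps)) / denom**2
    grad = -ddp * p * (1.0 - p)
    return 1.0 - dice, grad.astype(DTYPE)


class Adam:
    """Adaptive-moment estimation over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
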