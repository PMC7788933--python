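"""Pyramidal convolution (PyConv).

A PyConv layer runs n parallel convolution levels over the same input.
Kernel size grows from level 1 to level n while the kernel depth (the number
of input channels each kernel spans, ``in_channels / groups``) shrinks, so
large receptive fields come at small per-level cost.  The per-level outputs
are concatenated along the channel axis, and with same padding every level
preserves the spatial size.  A single level with kernel 3 and groups 1 is
exactly a standard 3x3 convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn

__all__ = [
    "PyConvLevel",
    "PyConvSpec",
    "make_pyconv_spec",
    "default_groups",
    "PyConv",
    "pyconv_forward",
]

DEFAULT_KERNELS = (3, 5, 7, 9)
DEFAULT_GROUPS = (1, 4, 8, 16)


@dataclass(frozen=True)
class PyConvLevel:
    """One pyramid level: a grouped ``kernel_size`` x ``kernel_size`` convolution."""

    kernel_size: int
    out_channels: int
    groups: int

    def validate(self, in_channels: int) -> None:
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd and >= 1, got {self.kernel_size}")
        if self.out_channels < 1:
            raise ValueError(f"out_channels must be >= 1, got {self.out_channels}")
        if self.groups < 1 or in_channels % self.groups:
            raise ValueError(
                f"groups={self.groups} does not divide in_channels={in_channels}")
        if self.out_channels % self.groups:
            raise ValueError(
                f"groups={self.groups} does not divide level out_channels={self.out_channels}")

    def depth(self, in_channels: int) -> int:
        """Kernel depth: number of input channels each kernel spans."""
        return in_channels // self.groups


@dataclass(frozen=True)
class PyConvSpec:
    """Validated per-layer pyramid configuration."""

    in_channels: int
    levels: tuple[PyConvLevel, ...]

    def __post_init__(self):
        if self.in_channels < 1:
            raise ValueError("in_channels must be positive")
        if not self.levels:
            raise ValueError("a PyConv spec needs at least one level")
        for lv in self.levels:
            lv.validate(self.in_channels)
        ks = [lv.kernel_size for lv in self.levels]
        if any(a >= b for a, b in zip(ks, ks[1:])):
            raise ValueError(f"kernel sizes must strictly increase, got {ks}")
        depths = [lv.depth(self.in_channels) for lv in self.levels]
        for i, (a, b) in enumerate(zip(depths, depths[1:])):
            if b > a:
                raise ValueError(
                    f"kernel depth increases from level {i + 1} ({a}) to level "
                    f"{i + 2} ({b}); depth must be non-increasing")

    @property
    def out_channels(self) -> int:
        return sum(lv.out_channels for lv in self.levels)

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def _split_out_channels(out_channels: int, n: int) -> list[int]:
    """Equal split; remainder channels go to level 1 (the cheapest kernel)."""
    base = out_channels // n
    if base == 0:
        raise ValueError(f"cannot split {out_channels} output channels over {n} levels")
    split = [base] * n
    split[0] += out_channels - base * n
    return split


def _feasible_groups(requested: int, in_channels: int, level_out: int) -> int:
    """Largest divisor of both channel counts that is <= requested.

    Handles narrow layers (e.g. the 1-channel stem) where the nominal group
    count is unrealizable; walking down by halving preserves power-of-two
    structure and hence the depth-non-increasing invariant.
    """
    g = max(1, requested)
    while g > 1 and (in_channels % g or level_out % g):
        g = g // 2 if g % 2 == 0 else 1
    return g


def make_pyconv_spec(in_channels: int, out_channels: int,
                     kernel_sizes=DEFAULT_KERNELS, groups=DEFAULT_GROUPS,
                     *, adapt_groups: bool = False) -> PyConvSpec:
    """Build a validated :class:`PyConvSpec` with an equal output split.

    Parameters
    ----------
    kernel_sizes
        Strictly increasing odd spatial sizes, one per level.
    groups
        Group count per level.  With ``adapt_groups=True`` each entry is
        treated as a ceiling and lowered to the largest feasible divisor of
        the layer's channel counts (used for narrow stages and the stem).
    """
    if in_channels < 1 or out_channels < 1:
        raise ValueError("channel counts must be positive")
    kernel_sizes = tuple(int(k) for k in kernel_sizes)
    groups = tuple(int(g) for g in groups)
    if len(kernel_sizes) != len(groups):
        raise ValueError(
            f"kernel_sizes and groups must have the same length, got "
            f"{len(kernel_sizes)} and {len(groups)}")
    split = _split_out_channels(out_channels, len(kernel_sizes))
    levels = []
    for k, g, oz in zip(kernel_sizes, groups, split):
        if adapt_groups:
            g = _feasible_groups(g, in_channels, oz)
        levels.append(PyConvLevel(kernel_size=k, out_channels=oz, groups=g))
    return PyConvSpec(in_channels=in_channels, levels=tuple(levels))


def default_groups(in_channels: int, out_channels: int,
                   n_levels: int = 4) -> tuple[int, ...]:
    """Maximal feasible grouping: the cheapest realizable pyramid.

    Each level uses the largest power of two dividing both ``in_channels``
    and its share of the output split; the resulting kernel depth is constant
    across levels (trivially non-increasing).
    """
    split = _split_out_channels(out_channels, n_levels)
    return tuple(_feasible_groups(max(in_channels, out_channels), in_channels, oz)
                 for oz in split)


class PyConv(_nn.Layer):
    """The pyramidal convolution layer (n parallel grouped convolutions).

    Levels are independent, so the layer output equals concatenating each
    level's grouped convolution computed on its own.
    """

    def __init__(self, spec: PyConvSpec, bias: bool = True, *,
                 rng: np.random.Generator, name: str = "pyconv"):
        self.spec = spec
        self.convs = [
            _nn.Conv2d(spec.in_channels, lv.out_channels, lv.kernel_size,
                       groups=lv.groups, bias=bias, rng=rng, name=f"{name}.level{i}")
            for i, lv in enumerate(spec.levels)
        ]

    def params(self):
        return [p for c in self.convs for p in c.params()]

    def forward(self, x, training=False):
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, got {x.shape[1]}")
        return np.concatenate([c.forward(x, training) for c in self.convs], axis=1)

    def backward(self, grad):
        splits = np.cumsum([lv.out_channels for lv in self.spec.levels])[:-1]
        parts = np.split(grad, splits, axis=1)
        gx = self.convs[0].backward(np.ascontiguousarray(parts[0]))
        for c, g in zip(self.convs[1:], parts[1:]):
            gx += c.backward(np.ascontiguousarray(g))
        return gx


def pyconv_forward(x: np.ndarray, spec: PyConvSpec,
                   weights: list[np.ndarray],
                   biases: list[np.ndarray] | None = None) -> np.ndarray:
    """Functional PyConv forward pass with caller-supplied kernels.

    ``x`` is (N, FM_i, H, W) or (FM_i, H, W); ``weights[z]`` has shape
    (groups, out/groups, in/groups, K_z, K_z) for level z.  Output spatial
    size equals input spatial size (same padding at every level).
    """
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if len(weights) != spec.n_levels:
        raise ValueError(f"expected {spec.n_levels} weight arrays, got {len(weights)}")
    rng = np.random.default_rng(0)
    outs = []
    for z, (lv, w) in enumerate(zip(spec.levels, weights)):
        conv = _nn.Conv2d(spec.in_channels, lv.out_channels, lv.kernel_size,
                          groups=lv.groups, bias=biases is not None, rng=rng)
        if w.shape != conv.weight.data.shape:
            raise ValueError(
                f"level {z + 1} weight shape {w.shape} != expected "
                f"{conv.weight.data.shape}")
        conv.weight.data = np.asarray(w)       # dtype preserved for precision
        if biases is not None:
            conv.bias.data = np.asarray(biases[z])
        outs.append(conv.forward(x))
    y = np.concatenate(outs, axis=1)
    return y[0] if squeeze else y
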