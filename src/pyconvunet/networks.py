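"""U-Net and PyConvU-Net builders.

Both networks share the classic encoder--decoder skeleton: ``n_downsamplings``
double-convolution blocks with 2x2 stride-2 max pooling, a double-conv
bottleneck, then a decoder of 2x2 stride-2 up-convolutions that halve the
channel count, concatenation with the same-resolution encoder feature (skip
connection), and a double-conv block; a 1x1 convolution plus sigmoid maps the
final feature map to a per-pixel foreground probability.  Every convolution
inside a double-conv block is same-padded and followed by batch
normalization and ReLU, so spatial size is preserved end to end.

PyConvU-Net keeps the skeleton and replaces each double-conv-block
convolution with a pyramidal convolution; up-convolutions and the 1x1 head
stay standard.  The default per-stage pyramid schedule is calibrated to the
published parameter budget: bottleneck-width layers use the canonical
depth-decreasing groups (1, 4, 8, 16) and every other layer uses maximal
feasible grouping (see :class:`CalibratedSchedule`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .pyconv import (DEFAULT_GROUPS, DEFAULT_KERNELS, PyConv, PyConvSpec,
                     make_pyconv_spec, default_groups)

__all__ = [
    "NetworkTopology",
    "CalibratedSchedule",
    "UniformSchedule",
    "build_unet",
    "build_pyconvunet",
    "predict",
    "binarize",
    "save_checkpoint",
    "load_checkpoint",
    "stage_plan",
    "ConvPlan",
    "UpconvPlan",
    "PoolPlan",
    "HeadPlan",
]


@dataclass(frozen=True)
class CalibratedSchedule:
    """Default PyConvU-Net pyramid schedule, calibrated to the parameter budget.

    Every PyConv layer uses ``kernels`` with an equal output-channel split.
    Layers whose output width equals the bottleneck width keep the canonical
    depth-decreasing pyramid ``pyramid_groups`` (lowered per level where the
    channel counts require it); all other layers use the largest feasible
    group count per level, which minimizes their parameter and MAC cost.
    Most of the network's capacity therefore sits in the bottleneck, where a
    parameter is cheapest in MACs.
    """

    kernels: tuple[int, ...] = DEFAULT_KERNELS
    pyramid_groups: tuple[int, ...] = DEFAULT_GROUPS

    def spec_for(self, in_channels: int, out_channels: int,
                 bottleneck_width: int) -> PyConvSpec:
        if out_channels == bottleneck_width:
            groups = self.pyramid_groups
        else:
            groups = default_groups(in_channels, out_channels, len(self.kernels))
        return make_pyconv_spec(in_channels, out_channels, self.kernels, groups,
                                adapt_groups=True)

    def to_dict(self) -> dict:
        return {"kind": "calibrated", "kernels": list(self.kernels),
                "pyramid_groups": list(self.pyramid_groups)}


@dataclass(frozen=True)
class UniformSchedule:
    """One group tuple for every PyConv layer (lowered where unrealizable)."""

    kernels: tuple[int, ...] = DEFAULT_KERNELS
    groups: tuple[int, ...] = DEFAULT_GROUPS

    def spec_for(self, in_channels: int, out_channels: int,
                 bottleneck_width: int) -> PyConvSpec:
        return make_pyconv_spec(in_channels, out_channels, self.kernels,
                                self.groups, adapt_groups=True)

    def to_dict(self) -> dict:
        return {"kind": "uniform", "kernels": list(self.kernels),
                "groups": list(self.groups)}


def schedule_from_dict(d: dict):
    if d["kind"] == "calibrated":
        return CalibratedSchedule(tuple(d["kernels"]), tuple(d["pyramid_groups"]))
    if d["kind"] == "uniform":
        return UniformSchedule(tuple(d["kernels"]), tuple(d["groups"]))
    raise ValueError(f"unknown schedule kind {d['kind']!r}")


@dataclass(frozen=True)
class NetworkTopology:
    """Structural description of a U-Net-family network."""

    in_channels: int = 1
    out_channels: int = 1
    base_width: int = 32
    n_downsamplings: int = 4
    conv_kind: str = "standard"          # "standard" | "pyconv"
    schedule: object = field(default_factory=CalibratedSchedule)

    def __post_init__(self):
        for name in ("in_channels", "out_channels", "base_width", "n_downsamplings"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.conv_kind not in ("standard", "pyconv"):
            raise ValueError(f"conv_kind must be 'standard' or 'pyconv', "
                             f"got {self.conv_kind!r}")

    @property
    def bottleneck_width(self) -> int:
        return self.base_width * 2**self.n_downsamplings

    @property
    def size_multiple(self) -> int:
        return 2**self.n_downsamplings

    def encoder_widths(self) -> list[int]:
        return [self.base_width * 2**i for i in range(self.n_downsamplings)]

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
            "base_width": self.base_width,
            "n_downsamplings": self.n_downsamplings,
            "conv_kind": self.conv_kind,
            "schedule": self.schedule.to_dict() if self.conv_kind == "pyconv" else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkTopology":
        sched = schedule_from_dict(d["schedule"]) if d.get("schedule") else CalibratedSchedule()
        return cls(in_channels=d["in_channels"], out_channels=d["out_channels"],
                   base_width=d["base_width"], n_downsamplings=d["n_downsamplings"],
                   conv_kind=d["conv_kind"], schedule=sched)


# ---------------------------------------------------------------------------
# Structural plan shared by the builder and the complexity accountant.

@dataclass(frozen=True)
class ConvPlan:
    """A double-conv-block convolution (BN + ReLU follow)."""
    name: str
    in_channels: int
    out_channels: int
    res_div: int                       # output resolution = input_size / res_div
    pyconv: PyConvSpec | None = None   # None -> standard 3x3


@dataclass(frozen=True)
class UpconvPlan:
    name: str
    in_channels: int
    out_channels: int
    res_div: int                       # of the OUTPUT feature map


@dataclass(frozen=True)
class PoolPlan:
    name: str
    channels: int
    res_div: int                       # of the INPUT feature map


@dataclass(frozen=True)
class HeadPlan:
    name: str
    in_channels: int
    out_channels: int
    res_div: int = 1


def stage_plan(topology: NetworkTopology) -> list:
    """Ordered structural records for every layer that carries cost."""
    t = topology
    plans: list = []
    pyconv = t.conv_kind == "pyconv"

    def conv(name, cin, cout, res_div):
        spec = None
        if pyconv:
            spec = t.schedule.spec_for(cin, cout, t.bottleneck_width)
        plans.append(ConvPlan(name, cin, cout, res_div, spec))

    res = 1
    cin = t.in_channels
    for i, w in enumerate(t.encoder_widths()):
        conv(f"enc{i}.conv1", cin, w, res)
        conv(f"enc{i}.conv2", w, w, res)
        plans.append(PoolPlan(f"enc{i}.pool", w, res))
        cin = w
        res *= 2
    wb = t.bottleneck_width
    conv("bottleneck.conv1", cin, wb, res)
    conv("bottleneck.conv2", wb, wb, res)
    cin = wb
    for i, w in enumerate(reversed(t.encoder_widths())):
        res //= 2
        plans.append(UpconvPlan(f"dec{i}.up", cin, w, res))
        conv(f"dec{i}.conv1", 2 * w, w, res)
        conv(f"dec{i}.conv2", w, w, res)
        cin = w
    plans.append(HeadPlan("head", cin, t.out_channels))
    return plans


# ---------------------------------------------------------------------------
# The network itself.

def _make_conv(plan: ConvPlan, rng) -> _nn.Layer:
    if plan.pyconv is None:
        return _nn.Conv2d(plan.in_channels, plan.out_channels, 3, bias=True,
                          rng=rng, name=plan.name)
    return PyConv(plan.pyconv, bias=True, rng=rng, name=plan.name)


class UNet:
    """Encoder--decoder segmentation network (standard or pyramidal convs).

    ``forward`` returns logits; :meth:`predict_proba` applies the sigmoid.
    Initialization is Kaiming fan-in for conv kernels, zero biases, BN scale
    1 / shift 0, all drawn from a caller-seeded generator.
    """

    def __init__(self, topology: NetworkTopology, seed: int = 0):
        self.topology = topology
        rng = np.random.default_rng(seed)
        t = topology

        def double(c1: ConvPlan, c2: ConvPlan) -> _nn.Sequential:
            return _nn.Sequential(
                _make_conv(c1, rng),
                _nn.BatchNorm2d(c1.out_channels, name=f"{c1.name}.bn"),
                _nn.ReLU(),
                _make_conv(c2, rng),
                _nn.BatchNorm2d(c2.out_channels, name=f"{c2.name}.bn"),
                _nn.ReLU(),
            )

        plans = stage_plan(topology)
        convs = {p.name: p for p in plans if isinstance(p, ConvPlan)}
        self.enc_blocks = [double(convs[f"enc{i}.conv1"], convs[f"enc{i}.conv2"])
                           for i in range(t.n_downsamplings)]
        self.pools = [_nn.MaxPool2d() for _ in range(t.n_downsamplings)]
        self.bottleneck = double(convs["bottleneck.conv1"], convs["bottleneck.conv2"])
        ups = {p.name: p for p in plans if isinstance(p, UpconvPlan)}
        self.ups = [_nn.ConvTranspose2d(ups[f"dec{i}.up"].in_channels,
                                        ups[f"dec{i}.up"].out_channels,
                                        rng=rng, name=f"dec{i}.up")
                    for i in range(t.n_downsamplings)]
        self.dec_blocks = [double(convs[f"dec{i}.conv1"], convs[f"dec{i}.conv2"])
                           for i in range(t.n_downsamplings)]
        self.head = _nn.Conv2d(t.base_width, t.out_channels, 1, bias=True,
                               rng=rng, name="head")
        self._skip_channels = None

    # -- parameter access ---------------------------------------------------
    def modules(self) -> list[_nn.Layer]:
        mods: list[_nn.Layer] = []
        mods.extend(self.enc_blocks)
        mods.extend(self.pools)
        mods.append(self.bottleneck)
        mods.extend(self.ups)
        mods.extend(self.dec_blocks)
        mods.append(self.head)
        return mods

    def params(self) -> list[_nn.Param]:
        return [p for m in self.modules() for p in m.params()]

    def num_parameters(self) -> int:
        """Trainable parameter census by enumerating instantiated arrays."""
        return sum(p.size for p in self.params())

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        m = self.topology.size_multiple
        h, w = x.shape[-2:]
        if h % m or w % m:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by {m} "
                f"(2^{self.topology.n_downsamplings} down-samplings)")
        if x.shape[1] != self.topology.in_channels:
            raise ValueError(f"expected {self.topology.in_channels} input "
                             f"channels, got {x.shape[1]}")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._check_input(x)
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = block.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, training)
            if x.shape[-2:] != skip.shape[-2:]:  # same padding guarantees this
                raise AssertionError("skip/up-sample spatial mismatch")
            x = np.concatenate([skip, x], axis=1)
            x = block.forward(x, training)
        self._skip_channels = [s.shape[1] for s in skips]
        return self.head.forward(x, training)

    def backward(self, grad: np.ndarray) -> None:
        grad = self.head.backward(grad)
        skip_grads = []
        for up, block, ch in zip(reversed(self.ups), reversed(self.dec_blocks),
                                 self._skip_channels):
            grad = block.backward(grad)
            gskip, gup = grad[:, :ch], grad[:, ch:]
            skip_grads.append(np.ascontiguousarray(gskip))
            grad = up.backward(np.ascontiguousarray(gup))
        grad = self.bottleneck.backward(grad)
        for pool, block, gskip in zip(reversed(self.pools),
                                      reversed(self.enc_blocks),
                                      reversed(skip_grads)):
            grad = pool.backward(grad)
            grad = block.backward(grad + gskip)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode forward pass through the sigmoid head."""
        return _nn.sigmoid(self.forward(x, training=False))

    # -- (de)serialization --------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {p.name: p.data for p in self.params()}
        assert len(arrays) == len(self.params()), "duplicate parameter names"
        for i, m in enumerate(self.modules()):
            for k, v in m.buffers().items():
                arrays[f"__buffer__.{i}.{k}"] = v
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.data = np.ascontiguousarray(arrays[p.name], dtype=_nn.DTYPE)
        buffered = {i: m for i, m in enumerate(self.modules()) if m.buffers()}
        for key, val in arrays.items():
            if not key.startswith("__buffer__."):
                continue
            _, idx, rest = key.split(".", 2)
            mod = buffered[int(idx)]
            # Sequential buffers are nested one level: "<layer_idx>.<name>"
            li, name = rest.split(".", 1)
            target = mod.layers[int(li)] if isinstance(mod, _nn.Sequential) else mod
            setattr(target, name, np.ascontiguousarray(val, dtype=_nn.DTYPE))


def build_unet(topology: NetworkTopology | None = None, seed: int = 0, **kw) -> UNet:
    """Baseline U-Net (standard 3x3 convolutions)."""
    if topology is None:
        topology = NetworkTopology(conv_kind="standard", **kw)
    if topology.conv_kind != "standard":
        raise ValueError("build_unet requires conv_kind='standard'")
    return UNet(topology, seed=seed)


def build_pyconvunet(topology: NetworkTopology | None = None, seed: int = 0, **kw) -> UNet:
    """PyConvU-Net: the same skeleton with pyramidal double-conv blocks."""
    if topology is None:
        kw.setdefault("schedule", CalibratedSchedule())
        topology = NetworkTopology(conv_kind="pyconv", **kw)
    if topology.conv_kind != "pyconv":
        raise ValueError("build_pyconvunet requires conv_kind='pyconv'")
    return UNet(topology, seed=seed)


# ---------------------------------------------------------------------------
# Inference utilities.

def predict(network: UNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel foreground probability map for one H x W image in [0, 1].

    The spatial size must be divisible by 2**n_downsamplings; no silent
    padding is performed.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a single-channel H x W image, got shape {image.shape}")
    x = image[None, None].astype(_nn.DTYPE)
    return network.predict_proba(x)[0, 0]


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map into a {0, 1} mask (>= convention)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie strictly inside (0, 1), got {threshold}")
    return (np.asarray(prob_map) >= threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# Checkpoints: a single .npz archive with the topology as JSON plus arrays.

def save_checkpoint(network: UNet, path) -> None:
    arrays = network.state_arrays()
    np.savez(path, __topology__=np.frombuffer(
        json.dumps(network.topology.to_dict()).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> UNet:
    with np.load(path) as npz:
        topo = NetworkTopology.from_dict(
            json.loads(bytes(npz["__topology__"]).decode()))
        net = UNet(topo, seed=0)
        net.load_state_arrays({k: npz[k] for k in npz.files if k != "__topology__"})
    return net
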