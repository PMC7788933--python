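"""Closed-form parameter and multiply-accumulate accounting.

For a standard convolution with square kernel K, ``params = K^2 * FM_i * FM_o``
(divided by the group count when grouped) and ``MACs = params * W * H`` with
W, H the output feature-map size.  For a pyramidal convolution the realizable
count sums ``K_z^2 * (FM_i / groups_z) * FM_oz`` over levels, while the
idealized accounting assigns level z the kernel depth ``FM_i / (K_z^2/K_1^2)``
so that every level costs ``K_1^2 * FM_i * FM_oz`` and the layer total
collapses to the standard convolution's budget exactly -- the cost-equality
property of the pyramid.  The idealized depths are generally not integers,
so instantiated layers realize the pyramid through integer group counts and
both accountings are exposed side by side.

``FLOPs`` throughout this package means multiply-accumulate counts (GMac =
1e9 MACs); the :class:`CountingConvention` records which surrounding op
classes (bias, BN, ReLU, pooling) are included, since published totals
depend on that choice.  :data:`TABLE_CONVENTION` is the calibrated
convention this repository documents for its headline numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .pyconv import PyConvSpec
from .networks import (NetworkTopology, UNet, stage_plan,
                       ConvPlan, UpconvPlan, PoolPlan, HeadPlan)

__all__ = [
    "ConvLayerSpec",
    "CountingConvention",
    "CostReport",
    "TABLE_CONVENTION",
    "params_standard",
    "flops_standard",
    "params_pyconv",
    "flops_pyconv",
    "count_network",
    "table3_topology",
]


@dataclass(frozen=True)
class ConvLayerSpec:
    """A (possibly grouped) standard convolution layer, for cost formulas."""

    kernel_size: int
    in_channels: int
    out_channels: int
    groups: int = 1
    width: int = 1
    height: int = 1

    def __post_init__(self):
        for name in ("kernel_size", "in_channels", "out_channels", "groups",
                     "width", "height"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise ValueError(f"groups={self.groups} must divide both channel counts")


def params_standard(spec: ConvLayerSpec) -> int:
    """Weight count of a standard/grouped convolution (bias and BN excluded)."""
    return (spec.kernel_size**2 * (spec.in_channels // spec.groups)
            * spec.out_channels)


def flops_standard(spec: ConvLayerSpec) -> int:
    """MACs of one forward pass: weight count times output pixels."""
    return params_standard(spec) * spec.width * spec.height


def params_pyconv(spec: PyConvSpec, mode: str = "realizable") -> int:
    """Weight count of a pyramidal convolution.

    ``realizable`` counts the instantiated grouped kernels.  ``idealized``
    uses the analytic depth ``FM_i/(K_z^2/K_1^2)``, under which every level
    costs ``K_1^2 * FM_i * FM_oz`` and the total equals the standard
    convolution's ``K_1^2 * FM_i * FM_o``.
    """
    if mode == "realizable":
        return sum(lv.kernel_size**2 * (spec.in_channels // lv.groups) * lv.out_channels
                   for lv in spec.levels)
    if mode == "idealized":
        k1 = spec.levels[0].kernel_size
        return sum(k1**2 * spec.in_channels * lv.out_channels for lv in spec.levels)
    raise ValueError(f"mode must be 'realizable' or 'idealized', got {mode!r}")


def flops_pyconv(spec: PyConvSpec, width: int, height: int,
                 mode: str = "realizable") -> int:
    if width < 1 or height < 1:
        raise ValueError("output size must be positive")
    return params_pyconv(spec, mode) * width * height


# ---------------------------------------------------------------------------
# Whole-network accounting.

@dataclass(frozen=True)
class CountingConvention:
    """Which op classes a MAC total includes, and how layers are measured.

    The defaults are the repository's calibrated convention: convolution
    MACs over output pixels; transposed-convolution MACs over input pixels
    (the true count for a 2x2 stride-2 up-convolution, whose output blocks
    are disjoint); one MAC per output element for each bias; 2 ops/element
    for batch normalization (scale and shift); 1 op/element for ReLU; 1 op
    per input element for 2x2 max pooling; sigmoid not counted.  Parameters
    count every trainable array: conv weights and biases plus 2 per BN
    channel.  ``table_stem_channels`` records that the published totals were
    measured with a 3-channel (RGB-loaded) input stem; see
    :func:`table3_topology`.
    """

    count_bias: bool = True
    bn_ops_per_element: int = 2
    relu_ops_per_element: int = 1
    pool_ops_per_element: int = 1
    sigmoid_ops_per_element: int = 0
    upconv_input_pixels: bool = True
    bn_params_per_channel: int = 2
    table_stem_channels: int = 3

    def to_dict(self) -> dict:
        return asdict(self)


TABLE_CONVENTION = CountingConvention()


@dataclass
class CostReport:
    """Per-layer and total parameter / MAC counts."""

    layers: list[tuple[str, int, int]]   # (layer id, params, macs)
    convention: CountingConvention
    input_size: tuple[int, int]
    mode: str

    @property
    def total_params(self) -> int:
        return sum(p for _, p, _ in self.layers)

    @property
    def total_macs(self) -> int:
        return sum(m for _, _, m in self.layers)

    @property
    def params_millions(self) -> float:
        return self.total_params / 1e6

    @property
    def gmacs(self) -> float:
        return self.total_macs / 1e9

    def to_tsv(self) -> str:
        lines = ["layer\tparams\tmacs"]
        lines += [f"{n}\t{p}\t{m}" for n, p, m in self.layers]
        lines.append(f"TOTAL\t{self.total_params}\t{self.total_macs}")
        return "\n".join(lines)

    def to_kv(self) -> str:
        h, w = self.input_size
        return "\n".join([
            f"input_size: {h}x{w}",
            f"mode: {self.mode}",
            f"total_params: {self.total_params}",
            f"params_millions: {self.params_millions:.4f}",
            f"total_macs: {self.total_macs}",
            f"gmacs: {self.gmacs:.4f}",
        ])


def count_network(network_or_topology, input_size,
                  convention: CountingConvention = TABLE_CONVENTION,
                  mode: str = "realizable") -> CostReport:
    """Analytic :class:`CostReport` for a network at a given input size.

    ``input_size`` is ``(H, W)`` or a single integer; both dimensions must
    be divisible by ``2**n_downsamplings``.
    """
    topo = (network_or_topology.topology
            if isinstance(network_or_topology, UNet) else network_or_topology)
    if not isinstance(topo, NetworkTopology):
        raise TypeError("expected a UNet or NetworkTopology")
    if isinstance(input_size, int):
        input_size = (input_size, input_size)
    H, W = input_size
    m = topo.size_multiple
    if H < m or W < m or H % m or W % m:
        raise ValueError(f"input size {H}x{W} must be divisible by {m}")
    c = convention
    rows: list[tuple[str, int, int]] = []
    for plan in stage_plan(topo):
        if isinstance(plan, ConvPlan):
            h, w = H // plan.res_div, W // plan.res_div
            n_out = plan.out_channels * h * w
            if plan.pyconv is None:
                pw = params_standard(ConvLayerSpec(3, plan.in_channels,
                                                   plan.out_channels))
            else:
                pw = params_pyconv(plan.pyconv, mode)
            params = pw + plan.out_channels + c.bn_params_per_channel * plan.out_channels
            macs = pw * h * w
            macs += (n_out if c.count_bias else 0)
            macs += (c.bn_ops_per_element + c.relu_ops_per_element) * n_out
            rows.append((plan.name, params, macs))
        elif isinstance(plan, PoolPlan):
            h, w = H // plan.res_div, W // plan.res_div
            rows.append((plan.name, 0,
                         c.pool_ops_per_element * plan.channels * h * w))
        elif isinstance(plan, UpconvPlan):
            h, w = H // plan.res_div, W // plan.res_div   # output size
            pw = 4 * plan.in_channels * plan.out_channels
            pixels = (h // 2) * (w // 2) if c.upconv_input_pixels else h * w
            macs = pw * pixels + (plan.out_channels * h * w if c.count_bias else 0)
            rows.append((plan.name, pw + plan.out_channels, macs))
        elif isinstance(plan, HeadPlan):
            h, w = H // plan.res_div, W // plan.res_div
            n_out = plan.out_channels * h * w
            macs = plan.in_channels * plan.out_channels * h * w
            macs += (n_out if c.count_bias else 0)
            macs += c.sigmoid_ops_per_element * n_out
            rows.append((plan.name, plan.in_channels * plan.out_channels
                         + plan.out_channels, macs))
    return CostReport(rows, c, (H, W), mode)


def table3_topology(model: str,
                    convention: CountingConvention = TABLE_CONVENTION) -> NetworkTopology:
    """The measurement topology behind the repository's headline MAC totals.

    Base width 32, four down-samplings, and the convention's 3-channel stem
    (datasets loaded as RGB in the measured configuration); ``model`` is
    ``"unet"`` or ``"pyconvunet"``.
    """
    if model not in ("unet", "pyconvunet"):
        raise ValueError(f"model must be 'unet' or 'pyconvunet', got {model!r}")
    return NetworkTopology(
        in_channels=convention.table_stem_channels, out_channels=1,
        base_width=32, n_downsamplings=4,
        conv_kind="standard" if model == "unet" else "pyconv")
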