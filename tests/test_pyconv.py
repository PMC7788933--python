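"""Pyramidal-convolution layer: spec validation, forward pass, oracle."""

import numpy as np
import pytest

from pyconvunet import _nn
from pyconvunet.pyconv import (PyConv, PyConvSpec, PyConvLevel,
                               default_groups, make_pyconv_spec, pyconv_forward)


def direct_grouped_conv(x, weight, k, groups, bias=None):
    """Nested-loop same-padded grouped convolution (independent oracle).

    x: (C, H, W); weight: (groups, out_per_group, in_per_group, k, k).
    """
    c, h, w = x.shape
    g, og, cg, _, _ = weight.shape
    pad = (k - 1) // 2
    xp = np.zeros((c, h + 2 * pad, w + 2 * pad))
    xp[:, pad:pad + h, pad:pad + w] = x
    out = np.zeros((g * og, h, w))
    for gi in range(g):
        for oi in range(og):
            for ci in range(cg):
                for u in range(k):
                    for v in range(k):
                        out[gi * og + oi] += (weight[gi, oi, ci, u, v]
                                              * xp[gi * cg + ci, u:u + h, v:v + w])
    if bias is not None:
        out += bias[:, None, None]
    return out


def level_weights(spec, rng):
    return [rng.normal(size=(lv.groups, lv.out_channels // lv.groups,
                             spec.in_channels // lv.groups,
                             lv.kernel_size, lv.kernel_size))
            for lv in spec.levels]


class TestSpecConstruction:
    def test_single_level_is_standard_conv_spec(self):
        spec = make_pyconv_spec(64, 64, [3], [1])
        assert spec.n_levels == 1
        assert spec.levels[0] == PyConvLevel(kernel_size=3, out_channels=64, groups=1)

    def test_default_schedule_arithmetic(self):
        spec = make_pyconv_spec(64, 64, [3, 5, 7, 9], [1, 4, 8, 16])
        assert [lv.out_channels for lv in spec.levels] == [16, 16, 16, 16]
        assert [lv.depth(64) for lv in spec.levels] == [64, 16, 8, 4]

    def test_remainder_channels_go_to_level_one(self):
        spec = make_pyconv_spec(16, 10, [3, 5], [1, 1])
        assert [lv.out_channels for lv in spec.levels] == [5, 5]
        spec = make_pyconv_spec(16, 11, [3, 5], [1, 1])
        assert [lv.out_channels for lv in spec.levels] == [6, 5]

    def test_stem_fallback_groups(self):
        spec = make_pyconv_spec(1, 32, adapt_groups=True)
        assert all(lv.groups == 1 for lv in spec.levels)

    @pytest.mark.parametrize("kwargs, match", [
        (dict(in_channels=64, out_channels=64, kernel_sizes=[4], groups=[1]), "odd"),
        (dict(in_channels=64, out_channels=64, kernel_sizes=[3, 5], groups=[3, 4]),
         "does not divide"),
        (dict(in_channels=64, out_channels=64, kernel_sizes=[5, 3], groups=[1, 1]),
         "strictly increase"),
        (dict(in_channels=64, out_channels=64, kernel_sizes=[3, 5], groups=[4, 1]),
         "depth increases"),
        (dict(in_channels=64, out_channels=64, kernel_sizes=[3, 5], groups=[1]),
         "same length"),
    ])
    def test_invalid_specs_rejected_with_distinct_diagnostics(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            make_pyconv_spec(**kwargs)

    def test_out_channels_sum_invariant(self):
        spec = make_pyconv_spec(32, 48, [3, 5, 7], [1, 2, 4])
        assert spec.out_channels == 48

    def test_default_groups_feasible_and_constant_depth(self):
        g = default_groups(64, 64)
        spec = make_pyconv_spec(64, 64, groups=g)
        depths = [lv.depth(64) for lv in spec.levels]
        assert len(set(depths)) == 1


class TestForward:
    def test_degenerate_single_level_equals_standard_conv(self, rng):
        spec = make_pyconv_spec(4, 4, [3], [1])
        w = level_weights(spec, rng)
        x = rng.random((4, 8, 8))
        conv = _nn.Conv2d(4, 4, 3, bias=False, rng=rng)
        conv.weight.data = w[0].astype(np.float32)
        expect = conv.forward(x[None].astype(np.float32))[0]
        got = pyconv_forward(x.astype(np.float32), spec, w)
        np.testing.assert_allclose(got, expect, atol=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_direct_loop_oracle(self, seed):
        """Twenty seeded configurations against the nested-loop oracle."""
        rng = np.random.default_rng(seed)
        cases = [
            (4, 4, [3, 5], [1, 2]),
            (8, 12, [3, 5, 7], [1, 2, 4]),
            (16, 16, [3, 5, 7, 9], [1, 2, 4, 4]),
            (6, 6, [3, 5], [1, 3]),
        ]
        cin, cout, ks, gs = cases[seed % len(cases)]
        spec = make_pyconv_spec(cin, cout, ks, gs)
        x = rng.normal(size=(cin, 8, 8))
        ws = level_weights(spec, rng)
        got = pyconv_forward(x, spec, ws)
        expect = np.concatenate(
            [direct_grouped_conv(x, w, lv.kernel_size, lv.groups)
             for lv, w in zip(spec.levels, ws)], axis=0)
        np.testing.assert_allclose(got, expect, atol=1e-5)

    def test_zero_weights_give_zero_output(self, rng):
        spec = make_pyconv_spec(4, 8, [3, 5], [1, 2])
        ws = [np.zeros_like(w) for w in level_weights(spec, rng)]
        y = pyconv_forward(rng.random((4, 8, 8)), spec, ws)
        assert y.shape == (8, 8, 8)
        assert np.all(y == 0)

    @pytest.mark.parametrize("hw", [(9, 9), (12, 16), (16, 12)])
    def test_spatial_size_preserved(self, rng, hw):
        spec = make_pyconv_spec(8, 16, [3, 5, 7, 9], [1, 2, 4, 4])
        x = rng.random((8, *hw))
        y = pyconv_forward(x, spec, level_weights(spec, rng))
        assert y.shape == (spec.out_channels, *hw)

    def test_parallel_level_decomposition_bitwise(self, rng):
        """Concatenating independently computed levels equals the layer call."""
        spec = make_pyconv_spec(8, 8, [3, 5], [2, 4])
        layer = PyConv(spec, bias=False, rng=np.random.default_rng(3))
        x = rng.random((2, 8, 12, 12)).astype(np.float32)
        whole = layer.forward(x)
        parts = np.concatenate([c.forward(x) for c in layer.convs], axis=1)
        assert np.array_equal(whole, parts)

    def test_channel_and_weight_shape_mismatches_rejected(self, rng):
        spec = make_pyconv_spec(4, 4, [3], [1])
        ws = level_weights(spec, rng)
        with pytest.raises(ValueError, match="weight shape"):
            pyconv_forward(rng.random((4, 8, 8)), spec, [ws[0][..., :2, :2]])
        layer = PyConv(spec, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="channels"):
            layer.forward(rng.random((1, 3, 8, 8)).astype(np.float32))
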