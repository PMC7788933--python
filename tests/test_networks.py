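"""Network builders: structure, shapes, determinism, checkpoints."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pyconvunet import _nn
from pyconvunet.complexity import count_network
from pyconvunet.networks import (NetworkTopology, binarize, build_pyconvunet,
                                 build_unet, load_checkpoint, predict,
                                 save_checkpoint, stage_plan, ConvPlan)


SMALL = dict(base_width=8, n_downsamplings=2)


class TestStructure:
    def test_encoder_channel_doubling(self):
        topo = NetworkTopology(base_width=32, n_downsamplings=4)
        assert topo.encoder_widths() == [32, 64, 128, 256]
        assert topo.bottleneck_width == 512

    def test_pyconv_replaces_only_double_conv_blocks(self):
        topo = NetworkTopology(conv_kind="pyconv", **SMALL)
        convs = [p for p in stage_plan(topo) if isinstance(p, ConvPlan)]
        assert all(p.pyconv is not None for p in convs)

    def test_pyconv_has_fewer_parameters_than_baseline(self):
        for kw in (dict(base_width=16, n_downsamplings=3),
                   dict(base_width=32, n_downsamplings=4)):
            u = build_unet(NetworkTopology(conv_kind="standard", **kw))
            p = build_pyconvunet(NetworkTopology(conv_kind="pyconv", **kw))
            assert p.num_parameters() < u.num_parameters()

    def test_analytic_params_equal_enumeration(self):
        for kind in ("standard", "pyconv"):
            topo = NetworkTopology(conv_kind=kind, **SMALL)
            net = (build_unet if kind == "standard" else build_pyconvunet)(topo)
            report = count_network(topo, 32)
            assert report.total_params == net.num_parameters()

    def test_invalid_topology_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            NetworkTopology(base_width=0)
        with pytest.raises(ValueError, match="conv_kind"):
            NetworkTopology(conv_kind="dilated")
        with pytest.raises(ValueError, match="standard"):
            build_unet(NetworkTopology(conv_kind="pyconv", **SMALL))


class TestForwardPass:
    @pytest.mark.parametrize("builder,kind",
                             [(build_unet, "standard"), (build_pyconvunet, "pyconv")])
    def test_output_shape_and_sigmoid_range(self, builder, kind):
        net = builder(NetworkTopology(conv_kind=kind, **SMALL), seed=0)
        img = np.random.default_rng(0).random((32, 32))
        prob = predict(net, img)
        assert prob.shape == (32, 32)
        assert np.all((prob > 0) & (prob < 1))

    def test_zero_weights_give_constant_half(self):
        net = build_pyconvunet(NetworkTopology(conv_kind="pyconv", **SMALL))
        for p in net.params():
            p.data[...] = 0
        prob = predict(net, np.random.default_rng(1).random((32, 32)))
        np.testing.assert_array_equal(prob, 0.5)

    def test_eval_mode_is_deterministic(self, rng):
        net = build_unet(NetworkTopology(**SMALL), seed=3)
        img = rng.random((32, 32))
        np.testing.assert_array_equal(predict(net, img), predict(net, img))

    def test_indivisible_size_raises_named_multiple(self):
        net = build_unet(NetworkTopology(base_width=8, n_downsamplings=4), seed=0)
        with pytest.raises(ValueError, match="divisible by 16"):
            predict(net, np.zeros((50, 50)))

    def test_same_seed_same_initialization(self):
        a = build_unet(NetworkTopology(**SMALL), seed=7)
        b = build_unet(NetworkTopology(**SMALL), seed=7)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestTrainingStep:
    def test_single_adam_step_decreases_loss(self, organ_samples):
        """Gradient flow: one optimization step on one sample lowers the loss."""
        net = build_unet(NetworkTopology(base_width=8, n_downsamplings=3), seed=0)
        s = organ_samples[0]
        x = s.image[None, None].astype(np.float32)
        t = s.mask[None, None].astype(np.float32)
        opt = _nn.Adam(net.params(), lr=1e-3)
        loss0, grad = _nn.bce_with_logits(net.forward(x, training=True), t)
        opt.zero_grad()
        net.backward(grad)
        opt.step()
        loss1, _ = _nn.bce_with_logits(net.forward(x, training=True), t)
        assert loss1 < loss0

    def test_backward_matches_finite_differences(self, tiny_unet, rng):
        x = rng.random((2, 1, 8, 8)).astype(np.float32)
        t = (rng.random((2, 1, 8, 8)) > 0.5).astype(np.float32)
        _, grad = _nn.bce_with_logits(tiny_unet.forward(x, training=True), t)
        for p in tiny_unet.params():
            p.grad[...] = 0
        tiny_unet.backward(grad)
        for p in (tiny_unet.params()[0], tiny_unet.params()[-2]):
            i = tuple(np.unravel_index(p.data.size // 2, p.data.shape))
            eps, orig = 1e-3, p.data[i]
            p.data[i] = orig + eps
            up, _ = _nn.bce_with_logits(tiny_unet.forward(x, training=True), t)
            p.data[i] = orig - eps
            dn, _ = _nn.bce_with_logits(tiny_unet.forward(x, training=True), t)
            p.data[i] = orig
            numeric = (up - dn) / (2 * eps)
            assert abs(numeric - p.grad[i]) <= 5e-3 * max(1.0, abs(numeric))


class TestBinarize:
    def test_boundary_and_simple_values(self):
        np.testing.assert_array_equal(binarize(np.full((2, 2), 0.5), 0.5),
                                      np.ones((2, 2), np.uint8))
        np.testing.assert_array_equal(binarize(np.array([0.2, 0.8]), 0.5),
                                      np.array([0, 1], np.uint8))

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_must_be_interior(self, bad):
        with pytest.raises(ValueError, match="threshold"):
            binarize(np.zeros((2, 2)), bad)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**32 - 1),
           st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    def test_monotone_in_threshold(self, seed, t1, t2):
        prob = np.random.default_rng(seed).random((6, 6))
        lo, hi = sorted((t1, t2))
        assert np.all(binarize(prob, hi) <= binarize(prob, lo))


class TestCheckpoint:
    def test_round_trip_is_bit_exact(self, tmp_path, organ_samples):
        net = build_pyconvunet(NetworkTopology(conv_kind="pyconv", **SMALL), seed=5)
        # perturb BN running stats so buffers are exercised too
        net.forward(organ_samples[0].image[None, None].astype(np.float32),
                    training=True)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path)
        other = load_checkpoint(path)
        assert other.topology == net.topology
        a, b = net.state_arrays(), other.state_arrays()
        assert a.keys() == b.keys()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])
        img = organ_samples[1].image
        np.testing.assert_array_equal(predict(net, img), predict(other, img))
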