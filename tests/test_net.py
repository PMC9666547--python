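"""Network architecture, attention blocks, and autograd correctness."""

import numpy as np
import pytest

from dimerdist.nn import autograd as ag
from dimerdist.nn.autograd import Tensor
from dimerdist.nn.layers import RCIN, Maxout, SEBlock, SpatialGate, _standardize
from dimerdist.nn.model import NetworkConfig, build_network, forward


class TestArchitectureConstants:
    def test_default_conv_layer_count_is_156(self):
        model = build_network(NetworkConfig(seed=0))
        assert model.conv_layer_count == 156

    def test_default_trunk_filters_are_64(self):
        model = build_network(NetworkConfig(seed=0))
        trunk = model.trunk_filter_counts()
        assert len(trunk) == 152  # 76 blocks x 2 convs
        assert set(trunk) == {64}

    def test_seeded_build_is_bit_identical(self):
        m1 = build_network(NetworkConfig(total_conv_layers=8, filters=8, seed=3))
        m2 = build_network(NetworkConfig(total_conv_layers=8, filters=8, seed=3))
        for (n1, p1), (n2, p2) in zip(m1.named_parameters(), m2.named_parameters()):
            assert n1 == n2
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_counting_rule_arithmetic(self):
        cfg = NetworkConfig(total_conv_layers=12, filters=8, seed=0)
        assert cfg.n_blocks == 4
        model = build_network(cfg)
        names = [n for n, _ in model.counted_conv_layers()]
        assert names[0] == "input" and names[1] == "maxout"
        assert names[-2:] == ["head_heavy", "head_cb"]

    def test_invalid_layer_count_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(total_conv_layers=7)

    def test_nonstandard_bins_warn_but_build(self):
        with pytest.warns(UserWarning, match="42-bin"):
            NetworkConfig(total_conv_layers=6, bins=10)

    def test_yaml_config_round_trip(self, tmp_path):
        from dimerdist.nn.model import config_from_yaml

        path = tmp_path / "net.yaml"
        path.write_text("total_conv_layers: 8\nfilters: 12\nseed: 4\n")
        cfg = config_from_yaml(path)
        assert cfg == NetworkConfig(total_conv_layers=8, filters=12, seed=4)
        path.write_text("layers: 8\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            config_from_yaml(path)


@pytest.fixture(scope="module")
def tiny_model():
    return build_network(NetworkConfig(total_conv_layers=6, filters=8, seed=1))


class TestForward:

    def test_softmax_heads_normalized(self, tiny_model):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 8, 186)).astype(np.float32)
        pred = forward(tiny_model, x)
        for vol in (pred.heavy_atom_probs, pred.cb_probs):
            assert vol.shape == (8, 8, 42)
            np.testing.assert_allclose(vol.sum(axis=-1), 1.0, atol=1e-5)
            assert (vol >= 0).all()

    def test_heterodimer_side_preserved(self, tiny_model):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5, 5, 186)).astype(np.float32)
        pred = forward(tiny_model, x)
        assert pred.heavy_atom_probs.shape == (5, 5, 42)

    def test_inference_is_deterministic(self, tiny_model):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((6, 6, 186)).astype(np.float32)
        p1, p2 = forward(tiny_model, x), forward(tiny_model, x)
        np.testing.assert_array_equal(p1.heavy_atom_probs, p2.heavy_atom_probs)

    def test_wrong_channel_count_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="feature shape mismatch"):
            tiny_model.forward_logits(np.zeros((4, 4, 10), dtype=np.float32))

    def test_checkpoint_round_trip(self, tiny_model, tmp_path):
        from dimerdist.nn.model import DistogramNetwork

        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, 4, 186)).astype(np.float32)
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        loaded = DistogramNetwork.load(path)
        np.testing.assert_array_equal(
            forward(tiny_model, x).heavy_atom_probs,
            forward(loaded, x).heavy_atom_probs,
        )


class TestMaxout:
    def test_max_per_consecutive_pair(self):
        x = Tensor(np.array([1.0, 3.0, 2.0, 0.0]).reshape(1, 1, 4))
        out = Maxout(2)(x)
        np.testing.assert_array_equal(out.data.ravel(), [3.0, 2.0])

    def test_single_group_is_identity(self):
        x = Tensor(np.arange(6.0).reshape(1, 1, 6))
        np.testing.assert_array_equal(Maxout(1)(x).data, x.data)

    def test_constant_channels_unchanged(self):
        x = Tensor(np.full((2, 2, 4), 5.0))
        np.testing.assert_array_equal(Maxout(2)(x).data, np.full((2, 2, 2), 5.0))

    def test_indivisible_channels_raise(self):
        with pytest.raises(ValueError, match="maxout group mismatch"):
            Maxout(2)(Tensor(np.zeros((1, 1, 3))))


class TestRCIN:
    def test_constant_input_yields_affine_bias(self):
        rng = np.random.default_rng(0)
        rcin = RCIN(3, rng)
        x = Tensor(np.full((4, 4, 3), 7.0))
        # branch outputs are beta (zero-centred input / epsilon-guarded std);
        # betas are zero at init, so fused output equals the fusion bias
        out = rcin(x)
        np.testing.assert_allclose(
            out.data, np.broadcast_to(rcin.fuse.bias.data, out.data.shape), atol=1e-5
        )

    def test_row_standardization_against_hand_oracle(self):
        x = Tensor(np.array([[1.0, 3.0], [5.0, 7.0]]).reshape(2, 2, 1))
        out = _standardize(x, axis=1).data[:, :, 0]
        for i, row in enumerate(np.array([[1.0, 3.0], [5.0, 7.0]])):
            m, sd = row.mean(), row.std()
            np.testing.assert_allclose(
                out[i], (row - m) / np.sqrt(sd**2 + 1e-6), rtol=1e-5
            )

    def test_output_channel_count_matches_input(self):
        rng = np.random.default_rng(1)
        rcin = RCIN(5, rng)
        x = Tensor(rng.standard_normal((3, 3, 5)).astype(np.float32))
        assert rcin(x).shape == (3, 3, 5)


class TestSEBlock:
    def test_gates_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        se = SEBlock(8, reduction=4, rng=rng)
        x = Tensor(rng.standard_normal((5, 5, 8)).astype(np.float32) * 5)
        g = se.gate(x).data
        assert (g > 0).all() and (g < 1).all()

    def test_zero_input_maps_to_zero(self):
        rng = np.random.default_rng(1)
        se = SEBlock(4, reduction=2, rng=rng)
        out = se(Tensor(np.zeros((3, 3, 4))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_squeeze_statistic_is_global_mean(self):
        rng = np.random.default_rng(2)
        se = SEBlock(4, reduction=2, rng=rng)
        x = rng.standard_normal((6, 6, 4)).astype(np.float32)
        doubled = x.copy()
        doubled[:, :, 2] *= 2
        sq = Tensor(x).mean(axis=(0, 1)).data
        sq2 = Tensor(doubled).mean(axis=(0, 1)).data
        np.testing.assert_allclose(sq2[2], 2 * sq[2], rtol=1e-5)
        changed = sq2 != sq
        assert changed[2] and not changed[[0, 1, 3]].any()


class TestSpatialGate:
    def test_gate_shape_is_spatial_by_one(self):
        rng = np.random.default_rng(0)
        sg = SpatialGate(rng)
        x = Tensor(rng.standard_normal((4, 6, 8)).astype(np.float32))
        assert sg.gate(x).shape == (4, 6, 1)

    def test_zero_input_maps_to_zero(self):
        rng = np.random.default_rng(1)
        sg = SpatialGate(rng)
        np.testing.assert_array_equal(sg(Tensor(np.zeros((3, 3, 4)))).data, 0.0)

    def test_channel_permutation_leaves_gate_unchanged(self):
        rng = np.random.default_rng(2)
        sg = SpatialGate(rng)
        x = rng.standard_normal((5, 5, 6)).astype(np.float32)
        perm = rng.permutation(6)
        g1 = sg.gate(Tensor(x)).data
        g2 = sg.gate(Tensor(x[:, :, perm])).data
        np.testing.assert_allclose(g1, g2, atol=1e-6)


def _numeric_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


class TestAutogradGradients:
    """Finite-difference checks of the hand-written backward passes."""

    def test_conv2d_gradients(self):
        rng = np.random.default_rng(0)
        x = Tensor(rng.standard_normal((4, 4, 2)).astype(np.float32), requires_grad=True)
        w = Tensor(rng.standard_normal((3, 3, 2, 3)).astype(np.float32) * 0.3, requires_grad=True)
        b = Tensor(np.zeros(3, dtype=np.float32), requires_grad=True)

        def loss_value():
            return float((ag.conv2d(Tensor(x.data), Tensor(w.data), Tensor(b.data)).data ** 2).sum())

        out = ag.conv2d(x, w, b)
        (out * out).sum().backward()
        for t in (x, w):
            num = _numeric_grad(lambda: loss_value(), t.data)
            np.testing.assert_allclose(t.grad, num, rtol=2e-2, atol=2e-2)

    def test_masked_cross_entropy_gradient(self):
        rng = np.random.default_rng(1)
        logits = Tensor(
            rng.standard_normal((3, 3, 5)).astype(np.float32), requires_grad=True
        )
        labels = rng.integers(0, 5, size=(3, 3))
        mask = rng.uniform(size=(3, 3)) < 0.6
        mask[0, 0] = True

        def loss_value():
            return float(
                ag.masked_softmax_cross_entropy(Tensor(logits.data), labels, mask).data
            )

        ag.masked_softmax_cross_entropy(logits, labels, mask).backward()
        num = _numeric_grad(lambda: loss_value(), logits.data)
        np.testing.assert_allclose(logits.grad, num, rtol=2e-2, atol=2e-3)

    def test_composite_block_gradient(self):
        """RCIN + SE + spatial gate + reductions, end to end."""
        rng = np.random.default_rng(2)
        rcin = RCIN(3, rng)
        se = SEBlock(3, reduction=1, rng=rng)
        sg = SpatialGate(rng)
        x0 = rng.standard_normal((3, 3, 3)).astype(np.float32)
        x = Tensor(x0.copy(), requires_grad=True)

        def run(inp):
            h = rcin(inp)
            h = se(h)
            h = sg(h)
            return (h * h).sum()

        run(x).backward()
        num = _numeric_grad(lambda: float(run(Tensor(x.data)).data), x.data)
        np.testing.assert_allclose(x.grad, num, rtol=5e-2, atol=5e-2)

    def test_unmasked_cells_receive_zero_gradient(self):
        rng = np.random.default_rng(3)
        logits = Tensor(
            rng.standard_normal((4, 4, 6)).astype(np.float32), requires_grad=True
        )
        labels = rng.integers(0, 6, size=(4, 4))
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 1] = mask[2, 3] = True
        ag.masked_softmax_cross_entropy(logits, labels, mask).backward()
        assert np.abs(logits.grad[~mask]).max() == 0.0
        assert np.abs(logits.grad[mask]).max() > 0.0
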