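"""Network architecture contracts, parameter counts, gradients, attention."""

import numpy as np
import pytest

from vesselseg.losses import LossSpec, get_loss
from vesselseg.nn.layers import Conv3d, ConvTranspose3d, GroupNorm
from vesselseg.nn.unet import AttentionGate, NetworkConfig, UNet3D


def analytic_param_count(cfg: NetworkConfig) -> int:
    """Closed-form parameter count, independent of the layer objects."""
    k3 = cfg.kernel_size ** 3

    def conv(cin, cout, k=k3):
        return cin * cout * k + cout

    def norm(c):
        return 2 * c

    total = 0
    filters = cfg.level_filters
    cin = cfg.in_channels
    for f in filters:
        total += conv(cin, f) + norm(f) + conv(f, f) + norm(f)
        cin = f
    ccur = filters[-1]
    for level in range(cfg.n_encoder_blocks - 2, -1, -1):
        f = filters[level]
        total += ccur * f * 8 + f            # transpose conv 2^3 kernel
        if cfg.skip_mode == "attention":
            total += conv(f, f) + conv(f, f) + conv(1, 1, 1)
        total += conv(2 * f, f) + conv(f, f)
        ccur = f
    total += conv(ccur, cfg.n_output_channels, 1)
    return total


class TestBuildNetwork:
    def test_default_block_counts_and_bottleneck(self):
        cfg = NetworkConfig()
        assert cfg.n_encoder_blocks == 6
        assert cfg.n_decoder_blocks == 5
        # five 2x poolings: 64 / 2^5 = 2 at the bottleneck
        assert cfg.input_shape[0] // 2 ** (cfg.n_encoder_blocks - 1) == 2

    def test_first_conv_param_count(self):
        conv = Conv3d(1, 8, 3, np.random.default_rng(0))
        assert conv.n_params == 1 * 8 * 27 + 8 == 224

    @pytest.mark.parametrize("skip_mode", ["concat", "attention"])
    def test_param_count_matches_closed_form(self, skip_mode):
        cfg = NetworkConfig(input_shape=(16, 16, 16), n_encoder_blocks=3,
                            n_decoder_blocks=2, base_filters=6,
                            skip_mode=skip_mode)
        net = UNet3D(cfg, np.random.default_rng(0))
        assert net.n_params == analytic_param_count(cfg)
        assert sum(r["n_params"] for r in net.summary()) == net.n_params

    def test_indivisible_input_shape_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(input_shape=(48, 48, 48), n_encoder_blocks=6,
                          n_decoder_blocks=5)

    def test_mismatched_block_counts_rejected(self):
        with pytest.raises(ValueError, match="n_decoder_blocks"):
            NetworkConfig(n_encoder_blocks=6, n_decoder_blocks=4)

    @pytest.mark.parametrize("shape,blocks", [((16, 16, 16), 3),
                                              ((32, 16, 16), 2),
                                              ((8, 8, 8), 2)])
    def test_output_spatial_shape_equals_input(self, shape, blocks):
        cfg = NetworkConfig(input_shape=shape, n_encoder_blocks=blocks,
                            n_decoder_blocks=blocks - 1, base_filters=2)
        net = UNet3D(cfg, np.random.default_rng(0))
        x = np.random.default_rng(1).random((1, *shape, 1),
                                            dtype=np.float32)
        probs = net.forward(x)
        assert probs.shape == (1, *shape, 2)

    def test_concat_and_attention_shapes_agree(self):
        shapes = {}
        for mode in ("concat", "attention"):
            cfg = NetworkConfig(input_shape=(16, 16, 16), n_encoder_blocks=3,
                                n_decoder_blocks=2, base_filters=4,
                                skip_mode=mode)
            net = UNet3D(cfg, np.random.default_rng(0))
            shapes[mode] = [r["output_shape"] for r in net.summary()]
        assert shapes["concat"] == shapes["attention"]


class TestForward:
    @pytest.fixture()
    def tiny_net(self):
        cfg = NetworkConfig(input_shape=(8, 8, 8), n_encoder_blocks=2,
                            n_decoder_blocks=1, base_filters=4,
                            dropout_rate=0.3)
        return UNet3D(cfg, np.random.default_rng(0))

    def test_softmax_sums_to_one(self, tiny_net, rng):
        x = rng.random((2, 8, 8, 8, 1), dtype=np.float32)
        probs = tiny_net.forward(x)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
        assert probs.min() >= 0.0

    def test_inference_mode_deterministic(self, tiny_net, rng):
        x = rng.random((1, 8, 8, 8, 1), dtype=np.float32)
        np.testing.assert_array_equal(tiny_net.forward(x),
                                      tiny_net.forward(x))

    def test_train_mode_dropout_stochastic(self, tiny_net, rng):
        x = rng.random((1, 8, 8, 8, 1), dtype=np.float32)
        out1 = tiny_net.forward(x, train=True, rng=np.random.default_rng(1))
        out2 = tiny_net.forward(x, train=True, rng=np.random.default_rng(2))
        assert not np.array_equal(out1, out2)

    def test_wrong_spatial_shape_rejected(self, tiny_net, rng):
        with pytest.raises(ValueError, match="spatial shape"):
            tiny_net.forward(rng.random((1, 4, 4, 4, 1)))


class TestAttentionGate:
    def test_zero_weights_give_half_k(self, rng):
        gate = AttentionGate(3, np.random.default_rng(0))
        for layer in gate.layers:
            for key in layer.params:
                layer.params[key][...] = 0.0
        q = rng.random((1, 4, 4, 4, 3), dtype=np.float32)
        k = rng.random((1, 4, 4, 4, 3), dtype=np.float32)
        out = gate.forward(q, k)
        np.testing.assert_allclose(out, 0.5 * k, atol=1e-7)

    def test_gating_bound_and_range(self, rng):
        gate = AttentionGate(4, np.random.default_rng(3))
        q = rng.random((2, 4, 4, 4, 4), dtype=np.float32)
        k = rng.standard_normal((2, 4, 4, 4, 4)).astype(np.float32)
        out = gate.forward(q, k)
        attn = gate.attention_map
        assert np.all(attn > 0.0) and np.all(attn < 1.0)
        assert np.all(np.abs(out) <= np.abs(k) + 1e-7)

    @pytest.mark.parametrize("shape", [(4, 4, 4), (2, 6, 4), (8, 2, 2)])
    def test_output_shape_follows_k(self, shape, rng):
        gate = AttentionGate(2, np.random.default_rng(0))
        q = rng.random((1, *shape, 2), dtype=np.float32)
        k = rng.random((1, *shape, 2), dtype=np.float32)
        assert gate.forward(q, k).shape == k.shape
        assert gate.attention_map.shape == (1, *shape, 1)

    def test_shape_mismatch_rejected(self, rng):
        gate = AttentionGate(2, np.random.default_rng(0))
        with pytest.raises(ValueError, match="mismatch"):
            gate.forward(rng.random((1, 4, 4, 4, 2)),
                         rng.random((1, 2, 2, 2, 2)))


class TestGradients:
    @pytest.mark.parametrize("skip_mode", ["concat", "attention"])
    def test_finite_difference_gradient_check(self, skip_mode):
        """Autodiff vs central finite differences on a 2-level toy network."""
        cfg = NetworkConfig(input_shape=(8, 8, 8), n_encoder_blocks=2,
                            n_decoder_blocks=1, base_filters=4,
                            dropout_rate=0.0, skip_mode=skip_mode)
        net = UNet3D(cfg, np.random.default_rng(0)).astype(np.float64)
        rng = np.random.default_rng(1)
        x = rng.random((2, 8, 8, 8, 1))
        truth = np.zeros((2, 8, 8, 8, 2))
        vessel = rng.random((2, 8, 8, 8)) > 0.7
        truth[..., 1] = vessel
        truth[..., 0] = ~vessel
        lossfn = get_loss(LossSpec(kind="dice_bce"))

        probs = net.forward(x)
        _, dloss = lossfn(probs, truth)
        net.zero_grad()
        net.backward(dloss)

        params = list(net.parameters())
        check_rng = np.random.default_rng(2)
        for _ in range(10):
            name, value, grad = params[check_rng.integers(len(params))]
            idx = tuple(check_rng.integers(s) for s in value.shape)
            eps = 1e-5
            orig = value[idx]
            value[idx] = orig + eps
            lp = lossfn(net.forward(x), truth)[0]
            value[idx] = orig - eps
            lm = lossfn(net.forward(x), truth)[0]
            value[idx] = orig
            fd = (lp - lm) / (2 * eps)
            denom = max(abs(fd) + abs(grad[idx]), 1e-8)
            assert abs(fd - grad[idx]) / denom < 1e-3, (name, idx)

    def test_checkpoint_state_dict_roundtrip(self, rng):
        cfg = NetworkConfig(input_shape=(8, 8, 8), n_encoder_blocks=2,
                            n_decoder_blocks=1, base_filters=4)
        net1 = UNet3D(cfg, np.random.default_rng(0))
        net2 = UNet3D(cfg, np.random.default_rng(99))
        net2.load_state_dict(net1.state_dict())
        x = rng.random((1, 8, 8, 8, 1), dtype=np.float32)
        np.testing.assert_array_equal(net1.forward(x), net2.forward(x))


class TestLayerPrimitives:
    def test_transpose_conv_doubles_resolution(self, rng):
        layer = ConvTranspose3d(3, 2, np.random.default_rng(0))
        x = rng.random((1, 4, 4, 4, 3), dtype=np.float32)
        assert layer.forward(x).shape == (1, 8, 8, 8, 2)

    def test_group_norm_clamps_groups_to_channels(self):
        gn = GroupNorm(2, groups=4)
        assert gn.groups == 2
        gn = GroupNorm(6, groups=4)   # 4 does not divide 6 -> fall back
        assert 6 % gn.groups == 0

    def test_group_norm_normalizes_per_group(self, rng):
        gn = GroupNorm(4, groups=2)
        x = (rng.random((2, 4, 4, 4, 4)) * 5 + 3).astype(np.float32)
        y = gn.forward(x)
        yg = y.reshape(2, -1, 2, 2)
        np.testing.assert_allclose(yg.mean(axis=(1, 3)), 0.0, atol=1e-4)
        np.testing.assert_allclose(yg.std(axis=(1, 3)), 1.0, atol=1e-3)
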