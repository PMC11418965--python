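"""Architecture contracts: shapes, attention normalization, residuals, gradients."""

import numpy as np
import pytest

from cryoenhance.network import (
    ArchitectureConfig,
    ConvResBlock,
    EPAAttention,
    EncoderStage,
    EnhancerNetwork,
    load_checkpoint,
    save_checkpoint,
)
from cryoenhance.nn import Tensor
from cryoenhance.training import masked_mse_tensor

TOY = ArchitectureConfig(base_channels=8, input_edge=16)


@pytest.fixture(scope="module")
def toy_net():
    return EnhancerNetwork(TOY, seed=3)


class TestShapes:
    def test_encoder_stage_halves_edge_and_widens(self):
        rng = np.random.default_rng(0)
        stage = EncoderStage(TOY, 0, rng)
        out = stage(Tensor(rng.random((1, 1, 16, 16, 16)).astype(np.float32)))
        assert out.shape == (1, 8, 8, 8, 8)

    def test_deepest_channels(self):
        assert TOY.channels_at(3) == 64
        cfg = ArchitectureConfig()
        assert cfg.channels_at(3) == 256

    def test_end_to_end_shapes(self, toy_net):
        for edge in (16, 32):
            x = np.random.default_rng(1).random((1, 1, edge, edge, edge))
            y = toy_net.predict(x.astype(np.float32))
            assert y.shape == (1, 1, edge, edge, edge)
            assert np.isfinite(y).all()

    def test_indivisible_edge_rejected(self, toy_net):
        with pytest.raises(ValueError, match="divisible"):
            toy_net.predict(np.zeros((1, 1, 24, 24, 24), dtype=np.float32))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureConfig(input_edge=40)  # 40 not divisible by 16
        with pytest.raises(ValueError):
            ArchitectureConfig(base_channels=6, epa_heads=4)

    def test_batchnorm_finite_on_zero_batch(self):
        rng = np.random.default_rng(2)
        stage = EncoderStage(TOY, 0, rng)
        out = stage(Tensor(np.zeros((2, 1, 16, 16, 16), dtype=np.float32)))
        assert np.isfinite(out.data).all()


class TestEPA:
    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        attn = EPAAttention(8, 4, spatial_proj=16, base_edge=4, rng=rng)
        x = Tensor(rng.random((2, 64, 8)).astype(np.float32))
        a_spatial, a_channel = attn.attention_weights(x, edge=4)
        np.testing.assert_allclose(a_spatial.data.sum(axis=-1), 1.0, atol=1e-5)
        np.testing.assert_allclose(a_channel.data.sum(axis=-1), 1.0, atol=1e-5)

    def test_channel_affinity_matches_brute_force_softmax(self):
        # single-head instance with fixed weights: the module's channel
        # affinity must equal softmax(Q^T K / tau) computed by hand
        rng = np.random.default_rng(1)
        attn = EPAAttention(4, 1, spatial_proj=8, base_edge=2, rng=rng)
        x = rng.random((1, 8, 4)).astype(np.float32)
        _, a_channel = attn.attention_weights(Tensor(x), edge=2)
        q = x @ attn.wq.weight.data + attn.wq.bias.data
        k = x @ attn.wk.weight.data + attn.wk.bias.data
        logits = q[0].T @ k[0] * float(attn.temperature.data.ravel()[0])
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        expected = e / e.sum(axis=-1, keepdims=True)
        np.testing.assert_allclose(a_channel.data[0, 0], expected, atol=1e-5)

    def test_output_shape_preserved(self):
        rng = np.random.default_rng(2)
        for c, edge in [(8, 4), (16, 6)]:
            attn = EPAAttention(c, 4, spatial_proj=16, base_edge=edge, rng=rng)
            x = Tensor(rng.random((2, edge**3, c)).astype(np.float32))
            assert attn.forward(x, edge).shape == (2, edge**3, c)


class TestConvRes:
    def test_shape_preserved_and_residual_identity(self):
        rng = np.random.default_rng(0)
        blk = ConvResBlock(8, rng)
        x = Tensor(rng.random((1, 8, 6, 6, 6)).astype(np.float32))
        assert blk(x).shape == x.shape
        # zero the convs and the norm gains: the block reduces to x + 0
        for name, p in blk.named_parameters():
            if "conv" in name or "gamma" in name:
                p.data[...] = 0.0
        np.testing.assert_allclose(blk(x).data, x.data, atol=1e-6)

    def test_gradient_flows_through_both_paths(self):
        rng = np.random.default_rng(1)
        blk = ConvResBlock(4, rng)
        x = Tensor(rng.random((1, 4, 5, 5, 5)).astype(np.float32), requires_grad=True)
        blk(x).sum().backward()
        assert x.grad is not None and np.abs(x.grad).max() > 0
        assert blk.conv1.weight.grad is not None
        assert np.abs(blk.conv1.weight.grad).max() > 0


class TestNetworkBehaviour:
    def test_eval_determinism(self, toy_net):
        x = np.random.default_rng(5).random((1, 1, 16, 16, 16)).astype(np.float32)
        y1 = toy_net.predict(x)
        y2 = toy_net.predict(x)
        np.testing.assert_array_equal(y1, y2)

    def test_batch_equivariance_in_eval(self, toy_net):
        rng = np.random.default_rng(6)
        x = rng.random((3, 1, 16, 16, 16)).astype(np.float32)
        y = toy_net.predict(x)
        y_perm = toy_net.predict(x[[2, 0, 1]])
        np.testing.assert_allclose(y_perm, y[[2, 0, 1]], atol=1e-5)

    def test_skip_connections_are_live(self):
        # zeroing the skip fusion's skip half must change the output
        net = EnhancerNetwork(TOY, seed=9)
        net.eval()
        x = np.random.default_rng(7).random((1, 1, 16, 16, 16)).astype(np.float32)
        base = net.predict(x)
        for dec in net.decoders:
            w = dec.reduce.weight.data
            w[:, w.shape[1] // 2:] = 0.0  # kill the concatenated skip channels
        ablated = net.predict(x)
        assert np.abs(base - ablated).max() > 1e-4

    def test_parameter_count_scales_quadratically_with_width(self):
        wide = EnhancerNetwork(ArchitectureConfig(base_channels=32, input_edge=48),
                               seed=0)
        narrow = EnhancerNetwork(ArchitectureConfig(base_channels=8, input_edge=48),
                                 seed=0)
        ratio = wide.parameter_count() / narrow.parameter_count()
        assert 10 <= ratio <= 25

    def test_single_gradient_step_decreases_loss(self, rng):
        from cryoenhance.nn import Adam

        # dropout off so both loss evaluations see the same function
        cfg = ArchitectureConfig(base_channels=8, input_edge=16, dropout_rate=0.0)
        net = EnhancerNetwork(cfg, seed=11)
        net.train()
        x = Tensor(rng.random((2, 1, 16, 16, 16)).astype(np.float32))
        target = rng.random((2, 1, 16, 16, 16)).astype(np.float32)
        loss0, _ = masked_mse_tensor(net(x), target)
        opt = Adam(net.parameters(), lr=1e-4)
        opt.zero_grad()
        loss0.backward()
        opt.step()
        loss1, _ = masked_mse_tensor(net(x), target)
        assert float(loss1.data) < float(loss0.data)

    def test_checkpoint_round_trip(self, tmp_path, toy_net):
        x = np.random.default_rng(8).random((1, 1, 16, 16, 16)).astype(np.float32)
        y = toy_net.predict(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, toy_net, extra={"note": "test"})
        net2, extra = load_checkpoint(path)
        assert extra["note"] == "test"
        np.testing.assert_allclose(net2.predict(x), y, atol=1e-6)
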