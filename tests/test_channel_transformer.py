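"""Channel transformer: token embedding geometry, the channel-attention
matrix oracle at tiny dimensions, stack composition, reconstruction index
mapping and the CCA gate."""

import numpy as np
import pytest

import tamunet.nn as nn
from tamunet.channel_transformer import (CCAGate, CCTLayer, CCTStack,
                                         ChannelTransformer, SkipReconstruction,
                                         channel_cross_attention,
                                         embed_multiscale_tokens)


def _feats(rng, base_hw=32, widths=(4, 8, 16, 32), n=1):
    return [nn.Tensor(rng.standard_normal((n, c, base_hw // 2**i, base_hw // 2**i))
                      .astype(np.float32))
            for i, c in enumerate(widths)]


class TestTokenEmbedding:
    def test_equal_token_counts_across_scales(self, rng):
        # spatial 32/16/8/4 with P=8 -> patch sizes 8/4/2/1 -> 16 tokens each
        bundle = embed_multiscale_tokens(_feats(rng), patch_size=8)
        assert [t.shape[1] for t in bundle.tokens] == [16] * 4

    def test_full_scale_token_count(self, rng):
        # 256/128/64/32 inputs with P=32 -> 64 tokens per scale
        feats = _feats(rng, base_hw=256, widths=(2, 2, 2, 2))
        bundle = embed_multiscale_tokens(feats, patch_size=32)
        assert [t.shape[1] for t in bundle.tokens] == [64] * 4

    def test_concat_channel_width_is_sum(self, rng):
        bundle = embed_multiscale_tokens(_feats(rng), patch_size=8)
        assert bundle.tsum.shape[2] == 4 + 8 + 16 + 32

    def test_constant_map_gives_constant_tokens(self):
        feats = [nn.Tensor(np.full((1, c, 32 // 2**i, 32 // 2**i), 2.5, dtype=np.float32))
                 for i, c in enumerate((4, 8, 16, 32))]
        bundle = embed_multiscale_tokens(feats, patch_size=8)
        for t in bundle.tokens:
            assert np.allclose(t.numpy(), 2.5, atol=1e-6)

    def test_indivisible_size_rejected(self, rng):
        feats = _feats(rng, base_hw=24)  # 24 not divisible by patch 16
        with pytest.raises(ValueError):
            embed_multiscale_tokens(feats, patch_size=16)


def _attention_oracle(q, k, v, c_sum):
    """Brute-force numpy transcription of the channel attention:
    scores = Q^T K / C_sum, instance-normalized, softmaxed over the C_sum
    axis, applied to V^T."""
    scores = q.T @ k / c_sum
    z = (scores - scores.mean()) / np.sqrt(scores.var() + 1e-5)
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    sim = e / e.sum(axis=-1, keepdims=True)
    return (sim @ v.T).T


class TestChannelCrossAttention:
    def test_softmax_rows_sum_to_one(self, rng):
        q = nn.Tensor(rng.standard_normal((1, 6, 3)).astype(np.float32))
        kv = nn.Tensor(rng.standard_normal((1, 6, 9)).astype(np.float32))
        scores = nn.matmul(nn.transpose(q, (0, 2, 1)), kv) * (1.0 / 9)
        sim = nn.softmax(nn.instance_norm(scores, axes=(-2, -1)), axis=-1).numpy()
        assert np.allclose(sim.sum(axis=-1), 1.0, atol=1e-6)

    def test_matches_explicit_matrix_oracle(self, rng):
        d, ci, c_sum = 2, 2, 5
        q = rng.standard_normal((d, ci)).astype(np.float32)
        k = rng.standard_normal((d, c_sum)).astype(np.float32)
        v = rng.standard_normal((d, c_sum)).astype(np.float32)
        out = channel_cross_attention(nn.Tensor(q[None]), nn.Tensor(k[None]),
                                      nn.Tensor(v[None]), c_sum).numpy()[0]
        assert np.allclose(out, _attention_oracle(q, k, v, c_sum), atol=1e-5)

    def test_token_permutation_equivariance(self, rng):
        d = 6
        q = rng.standard_normal((1, d, 3)).astype(np.float32)
        kv = rng.standard_normal((1, d, 7)).astype(np.float32)
        out = channel_cross_attention(nn.Tensor(q), nn.Tensor(kv),
                                      nn.Tensor(kv), 7).numpy()
        perm = np.random.default_rng(0).permutation(d)
        out_p = channel_cross_attention(nn.Tensor(q[:, perm]), nn.Tensor(kv[:, perm]),
                                        nn.Tensor(kv[:, perm]), 7).numpy()
        assert np.allclose(out[:, perm], out_p, atol=1e-5)

    def test_dimension_mismatch_rejected(self, rng):
        q = nn.Tensor(rng.standard_normal((1, 4, 3)).astype(np.float32))
        kv = nn.Tensor(rng.standard_normal((1, 6, 7)).astype(np.float32))
        with pytest.raises(ValueError):
            channel_cross_attention(q, kv, kv, 7)


class TestCCTStack:
    def test_output_shapes_match_inputs(self, rng):
        widths = (4, 8, 16, 32)
        stack = CCTStack(widths, n_layers=2, n_heads=2)
        bundle = embed_multiscale_tokens(_feats(rng, widths=widths), patch_size=8)
        outs = stack(bundle)
        for t, o in zip(bundle.tokens, outs):
            assert o.shape == t.shape

    def test_single_head_layer_equals_manual_composition(self, rng):
        widths = (3, 5, 7, 9)
        layer = CCTLayer(widths, n_heads=1)
        bundle = embed_multiscale_tokens(_feats(rng, widths=widths), patch_size=8)
        outs = layer(bundle.tokens, bundle.tsum)
        c_sum = sum(widths)
        tsum_n = layer.sum_norm(bundle.tsum)
        for i, t in enumerate(bundle.tokens):
            q, k, v = layer.attn.head_projections(
                i, layer.attn_norms[i](t), tsum_n)[0]
            mca = channel_cross_attention(q, k, v, c_sum)
            u = t + mca
            manual = u + layer.mlps[i](layer.ffn_norms[i](u))
            assert np.allclose(outs[i].numpy(), manual.numpy(), atol=1e-5)

    def test_zero_layers_is_identity(self, rng):
        stack = CCTStack((4, 8, 16, 32), n_layers=0)
        bundle = embed_multiscale_tokens(_feats(rng), patch_size=8)
        outs = stack(bundle)
        for t, o in zip(bundle.tokens, outs):
            assert np.array_equal(o.numpy(), t.numpy())


class TestSkipReconstruction:
    def test_output_matches_encoder_resolution(self, rng):
        rec = SkipReconstruction(4)
        tokens = nn.Tensor(rng.standard_normal((1, 16, 4)).astype(np.float32))
        assert rec(tokens, grid=4, out_h=32, out_w=32).shape == (1, 4, 32, 32)

    def test_constant_tokens_spatially_constant_before_conv(self):
        tokens = nn.Tensor(np.full((1, 9, 2), 1.5, dtype=np.float32))
        x = nn.reshape(nn.transpose(tokens, (0, 2, 1)), (1, 2, 3, 3))
        up = nn.interpolate_bilinear(x, 12, 12).numpy()
        assert np.allclose(up, 1.5, atol=1e-6)

    def test_one_hot_token_maps_to_its_patch(self):
        grid, patch = 4, 4
        tokens = np.zeros((1, grid * grid, 1), dtype=np.float32)
        tokens[0, 1 * grid + 2, 0] = 1.0  # token at grid row 1, col 2
        x = nn.reshape(nn.transpose(nn.Tensor(tokens), (0, 2, 1)), (1, 1, grid, grid))
        up = nn.interpolate_bilinear(x, grid * patch, grid * patch).numpy()[0, 0]
        # mass concentrates around patch (1, 2): its centre pixel is the peak
        r, c = np.unravel_index(np.argmax(up), up.shape)
        assert 1 * patch <= r < 2 * patch
        assert 2 * patch <= c < 3 * patch


class TestCCAGate:
    def test_gate_values_strictly_in_unit_interval(self, rng):
        gate = CCAGate(4)
        o = nn.Tensor(rng.standard_normal((2, 4, 8, 8)).astype(np.float32))
        d = nn.Tensor(rng.standard_normal((2, 4, 8, 8)).astype(np.float32))
        eta_o = nn.mean(o, axis=(2, 3))
        eta_d = nn.mean(d, axis=(2, 3))
        m = gate.lin_o(nn.relu(eta_o)) + gate.lin_d(nn.relu(eta_d))
        g = nn.sigmoid(m).numpy()
        assert np.all(g > 0) and np.all(g < 1)

    def test_zero_skip_stays_zero(self, rng):
        gate = CCAGate(3)
        o = nn.Tensor(np.zeros((1, 3, 6, 6), dtype=np.float32))
        d = nn.Tensor(rng.standard_normal((1, 3, 6, 6)).astype(np.float32))
        assert np.all(gate(o, d).numpy() == 0)

    def test_eta_of_constant_map_is_the_constant(self):
        x = nn.Tensor(np.full((1, 2, 5, 5), 3.25, dtype=np.float32))
        eta = nn.mean(x, axis=(2, 3)).numpy()
        assert np.allclose(eta, 3.25, atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        gate = CCAGate(3)
        o = nn.Tensor(rng.standard_normal((1, 3, 6, 6)).astype(np.float32))
        d = nn.Tensor(rng.standard_normal((1, 3, 4, 4)).astype(np.float32))
        with pytest.raises(ValueError):
            gate(o, d)


class TestChannelConservation:
    def test_widths_preserved_through_transform_and_gate(self, rng):
        widths = (4, 8, 16, 32)
        ct = ChannelTransformer(widths, patch_size=8, n_layers=1, n_heads=2)
        feats = _feats(rng, widths=widths)
        outs = ct.transform_skips(feats)
        for f, o in zip(feats, outs):
            assert o.shape == f.shape
            gated = ct.gate(feats.index(f), o, o)
            assert gated.shape == f.shape
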