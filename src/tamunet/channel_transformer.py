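"""Channel-wise cross-fusion transformer (CCT) skip connections and the
channel-wise cross-attention (CCA) decoder gate.

The four encoder skip feature maps are patch-embedded (average pooling over
non-overlapping patches of size P, P/2, P/4, P/8, preserving channel width)
into token sets T1..T4 that all share the same token count d.  Their
channel-wise concatenation T_sum (d x C_sum, C_sum = sum Ci) provides the
shared key and value; each scale's tokens provide the queries.  Attention is
computed along the *channel* axis: the similarity Qi^T K / C_sum is
instance-normalized, softmaxed over the C_sum axis and applied to V^T, so
each scale keeps its own channel width and d tokens.  N head outputs are
averaged, a residual MLP is applied, and the block repeats L times.  The
resulting tokens are reshaped to the patch grid, bilinearly upsampled and
convolved back to each skip's resolution, then gated channel-wise against
the upsampled decoder features (CCA) before concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass
class TokenBundle:
    """Per-scale token sets plus their channel-wise concatenation.

    Each entry of ``tokens`` has shape (N, d, Ci); ``tsum`` is (N, d, C_sum).
    ``grids`` records the per-scale patch-grid side length for reconstruction.
    """

    tokens: list
    tsum: "nn.Tensor"
    patch_size: int
    grids: list

    @property
    def token_count(self) -> int:
        return self.tokens[0].shape[1]

    @property
    def channel_widths(self) -> list:
        return [t.shape[2] for t in self.tokens]


def embed_multiscale_tokens(features, patch_size: int) -> TokenBundle:
    """Patch-embed the four skip feature maps into equal-count token sets.

    Scale i (spatial size halving per stage) uses patch size P / 2^i, so all
    four scales map to the same token grid; embedding is average pooling over
    non-overlapping patches, preserving channel width.
    """
    if patch_size % 8:
        raise ValueError(f"patch size must be divisible by 8, got {patch_size}")
    tokens, grids = [], []
    for i, f in enumerate(features):
        p = patch_size // (2**i)
        h, w = f.shape[2], f.shape[3]
        if h % p or w % p:
            raise ValueError(f"scale {i}: spatial size {(h, w)} not divisible by patch {p}")
        pooled = nn.avg_pool2d(f, p)  # (N, C, g, g)
        n, c, gh, gw = pooled.shape
        grids.append(gh)
        tokens.append(nn.transpose(nn.reshape(pooled, (n, c, gh * gw)), (0, 2, 1)))
    counts = {t.shape[1] for t in tokens}
    if len(counts) != 1:
        raise ValueError(f"token counts differ across scales: {sorted(counts)}")
    return TokenBundle(tokens, nn.concat(tokens, axis=2), patch_size, grids)


def channel_cross_attention(qi, k, v, c_sum: int):
    """One head of channel attention on token matrices.

    qi: (N, d, Ci); k, v: (N, d, C_sum).  The similarity Qi^T K is scaled by
    C_sum (as specified — not sqrt(C_sum)), instance-normalized over each
    (Ci, C_sum) matrix, softmaxed along the C_sum axis and applied to V^T;
    the output is returned token-major, (N, d, Ci).
    """
    if qi.shape[1] != k.shape[1] or k.shape != v.shape:
        raise ValueError("token-count/shape mismatch between queries and key/value")
    scores = nn.matmul(nn.transpose(qi, (0, 2, 1)), k) * (1.0 / c_sum)  # (N, Ci, C_sum)
    sim = nn.softmax(nn.instance_norm(scores, axes=(-2, -1)), axis=-1)
    out = nn.matmul(sim, nn.transpose(v, (0, 2, 1)))  # (N, Ci, d)
    return nn.transpose(out, (0, 2, 1))


class MultiHeadChannelAttention(nn.Module):
    """N independent projection sets; per-scale outputs averaged over heads.

    The per-head projection matrices are stored stacked along the output axis
    (one Linear of width N*C per input), so all heads are projected in a
    single GEMM; head j's block is the slice [j*C:(j+1)*C].  The key and
    value projections of the concatenated tokens are shared by all scales.
    """

    def __init__(self, channel_widths, n_heads: int = 4):
        super().__init__()
        self.n_heads = n_heads
        self.widths = tuple(channel_widths)
        c_sum = sum(channel_widths)
        self.c_sum = c_sum
        self.query = nn.ModuleList(
            [nn.Linear(c, n_heads * c, bias=False) for c in channel_widths]
        )
        self.key = nn.Linear(c_sum, n_heads * c_sum, bias=False)
        self.value = nn.Linear(c_sum, n_heads * c_sum, bias=False)

    def head_projections(self, i, t, tsum):
        """(Q, K, V) slices for every head at scale i."""
        c, cs = self.widths[i], self.c_sum
        q_all, k_all, v_all = self.query[i](t), self.key(tsum), self.value(tsum)
        return [(q_all[:, :, j * c:(j + 1) * c],
                 k_all[:, :, j * cs:(j + 1) * cs],
                 v_all[:, :, j * cs:(j + 1) * cs]) for j in range(self.n_heads)]

    def __call__(self, tokens, tsum):
        k_all = self.key(tsum)
        v_all = self.value(tsum)
        cs = self.c_sum
        outs = []
        for i, t in enumerate(tokens):
            c = self.widths[i]
            q_all = self.query[i](t)
            acc = None
            for j in range(self.n_heads):
                ca = channel_cross_attention(q_all[:, :, j * c:(j + 1) * c],
                                             k_all[:, :, j * cs:(j + 1) * cs],
                                             v_all[:, :, j * cs:(j + 1) * cs], cs)
                acc = ca if acc is None else acc + ca
            outs.append(acc * (1.0 / self.n_heads))
        return outs


class TokenMLP(nn.Module):
    """Transformer feed-forward: hidden expansion x4, GELU."""

    def __init__(self, dim: int, expansion: int = 4):
        super().__init__()
        self.fc1 = nn.Linear(dim, expansion * dim)
        self.fc2 = nn.Linear(expansion * dim, dim)

    def __call__(self, x):
        return self.fc2(nn.gelu(self.fc1(x)))


class CCTLayer(nn.Module):
    """One transformer layer: pre-norm averaged multi-head channel attention
    with a residual, then a pre-norm residual MLP:

        u_i = T_i + MCA_i(LN(T_1..4), LN(T_sum))
        T_i <- u_i + MLP_i(LN(u_i))

    The normalizations are declared but left out of the printed update
    equations upstream; they are required for stable optimization."""

    def __init__(self, channel_widths, n_heads: int = 4, mlp_expansion: int = 4):
        super().__init__()
        self.attn = MultiHeadChannelAttention(channel_widths, n_heads)
        self.attn_norms = nn.ModuleList([nn.LayerNorm(c) for c in channel_widths])
        self.sum_norm = nn.LayerNorm(sum(channel_widths))
        self.ffn_norms = nn.ModuleList([nn.LayerNorm(c) for c in channel_widths])
        self.mlps = nn.ModuleList([TokenMLP(c, mlp_expansion) for c in channel_widths])

    def __call__(self, tokens, tsum):
        normed = [self.attn_norms[i](t) for i, t in enumerate(tokens)]
        mca = self.attn(normed, self.sum_norm(tsum))
        out = []
        for i, m in enumerate(mca):
            u = tokens[i] + m
            out.append(u + self.mlps[i](self.ffn_norms[i](u)))
        return out


class CCTStack(nn.Module):
    """L stacked CCT layers; L=0 is the identity on the token bundle."""

    def __init__(self, channel_widths, n_layers: int = 4, n_heads: int = 4,
                 mlp_expansion: int = 4):
        super().__init__()
        self.layers = nn.ModuleList(
            [CCTLayer(channel_widths, n_heads, mlp_expansion) for _ in range(n_layers)]
        )

    def __call__(self, bundle: TokenBundle):
        tokens = bundle.tokens
        for layer in self.layers:
            tsum = nn.concat(tokens, axis=2)
            tokens = layer(tokens, tsum)
        return tokens


class SkipReconstruction(nn.Module):
    """Tokens -> patch grid -> bilinear upsample -> 3x3 conv (+BN+ReLU)."""

    def __init__(self, channels: int):
        super().__init__()
        self.conv = nn.Conv2d(channels, channels, 3, padding="same", bias=False)
        self.bn = nn.BatchNorm2d(channels)

    def __call__(self, tokens, grid: int, out_h: int, out_w: int):
        n, d, c = tokens.shape
        if grid * grid != d:
            raise ValueError(f"token count {d} is not a {grid}x{grid} grid")
        x = nn.reshape(nn.transpose(tokens, (0, 2, 1)), (n, c, grid, grid))
        x = nn.interpolate_bilinear(x, out_h, out_w)
        return nn.relu(self.bn(self.conv(x)))


class CCAGate(nn.Module):
    """Channel-wise cross-attention gate on a reconstructed skip.

    M = L1 relu(eta(O)) + L2 relu(eta(D)) with eta = spatial global average
    pooling; the two linear maps are full-width (no channel reduction) and
    independent.  The sigmoid of M gates O channel-wise before the decoder
    concatenation.
    """

    def __init__(self, channels: int):
        super().__init__()
        self.lin_o = nn.Linear(channels, channels, bias=False)
        self.lin_d = nn.Linear(channels, channels, bias=False)

    def __call__(self, o, d):
        if o.shape != d.shape:
            raise ValueError(f"skip {o.shape} / decoder {d.shape} shape mismatch")
        eta_o = nn.mean(o, axis=(2, 3))  # (N, C)
        eta_d = nn.mean(d, axis=(2, 3))
        m = self.lin_o(nn.relu(eta_o)) + self.lin_d(nn.relu(eta_d))
        gate = nn.sigmoid(m)
        n, c = gate.shape
        return o * nn.reshape(gate, (n, c, 1, 1))


class ChannelTransformer(nn.Module):
    """CCT + per-scale reconstruction + CCA gates, the full skip replacement."""

    def __init__(self, channel_widths, patch_size: int, n_layers: int = 4,
                 n_heads: int = 4, mlp_expansion: int = 4):
        super().__init__()
        self.patch_size = patch_size
        self.cct = CCTStack(channel_widths, n_layers, n_heads, mlp_expansion)
        self.reconstruct = nn.ModuleList([SkipReconstruction(c) for c in channel_widths])
        self.gates = nn.ModuleList([CCAGate(c) for c in channel_widths])

    def transform_skips(self, features):
        """Run CCT over the four skips; returns reconstructed maps O1..O4."""
        bundle = embed_multiscale_tokens(features, self.patch_size)
        tokens = self.cct(bundle)
        outs = []
        for i, t in enumerate(tokens):
            h, w = features[i].shape[2], features[i].shape[3]
            outs.append(self.reconstruct[i](t, bundle.grids[i], h, w))
        return outs

    def gate(self, i: int, o, d):
        return self.gates[i](o, d)
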