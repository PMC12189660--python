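"""Atrous spatial pyramid pooling (ASPP) bottleneck.

Five parallel branches — a 1x1 convolution, three 3x3 convolutions dilated at
rates 6/12/18 (the DeepLabv3+ defaults; the rates are configurable), and a
global-average-pooling branch whose pooled vector is 1x1-convolved and
bilinearly restored to the input resolution — are concatenated along
channels (5C'), batch-normalized, and projected by a final 1x1 convolution
to the bottleneck width.
"""

from __future__ import annotations

from . import nn

ASPP_RATES = (6, 12, 18)


def dilated_conv2d(x, weight, bias=None, rate: int = 1):
    """"Same"-padded 3x3 dilated convolution; rate=1 is an ordinary conv."""
    if rate < 1:
        raise ValueError(f"dilation rate must be >= 1, got {rate}")
    return nn.conv2d(x, weight, bias, padding="same", dilation=rate)


class ASPP(nn.Module):
    def __init__(self, in_ch: int, branch_ch: int | None = None,
                 out_ch: int | None = None, rates=ASPP_RATES):
        super().__init__()
        branch_ch = branch_ch or in_ch
        out_ch = out_ch or in_ch
        self.rates = tuple(rates)
        self.conv1x1 = nn.Conv2d(in_ch, branch_ch, 1)
        self.dilated = nn.ModuleList(
            [nn.Conv2d(in_ch, branch_ch, 3, padding="same", dilation=r) for r in self.rates]
        )
        self.gap_proj = nn.Conv2d(in_ch, branch_ch, 1)
        self.bn = nn.BatchNorm2d(5 * branch_ch)
        self.project = nn.Conv2d(5 * branch_ch, out_ch, 1)

    def gap_branch(self, x):
        """Per-channel global mean -> 1x1 conv -> bilinear restore to HxW."""
        h, w = x.shape[2], x.shape[3]
        pooled = nn.mean(x, axis=(2, 3), keepdims=True)
        return nn.interpolate_bilinear(self.gap_proj(pooled), h, w)

    def __call__(self, x):
        branches = [self.conv1x1(x)]
        for conv in self.dilated:
            branches.append(conv(x))
        branches.append(self.gap_branch(x))
        cat = nn.concat(branches, axis=1)
        return self.project(self.bn(cat))
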