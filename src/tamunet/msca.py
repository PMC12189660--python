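"""Multi-scale convolutional attention (MSCA).

A pyramid of depth-wise convolutions re-weights the encoder feature map:
a 5x5 depth-wise convolution extracts local context (A0); three separable
depth-wise branches with kernel lengths 7, 11 and 21 (each a 1xk followed by
a kx1 depth-wise convolution, the rank-1 surrogate for a kxk kernel) add
multi-scale context (A1..A3); their sum passes through a 1x1 convolution
whose output is the attention map, applied to the input by element-wise
(Hadamard) product.  No squashing is applied to the attention map.
"""

from __future__ import annotations

from . import nn

MSCA_BRANCH_KERNELS = (7, 11, 21)


class SeparableBranch(nn.Module):
    """Depth-wise 1xk followed by kx1 convolution, "same" padding."""

    def __init__(self, channels: int, k: int):
        super().__init__()
        if k % 2 == 0 or k < 3:
            raise ValueError(f"separable branch kernel must be odd and >= 3, got {k}")
        self.k = k
        self.conv_1xk = nn.Conv2d(channels, channels, (1, k), groups=channels, padding="same")
        self.conv_kx1 = nn.Conv2d(channels, channels, (k, 1), groups=channels, padding="same")

    def __call__(self, x):
        return self.conv_kx1(self.conv_1xk(x))


def separable_branch(x, weight_1xk, weight_kx1, bias_1xk=None, bias_kx1=None):
    """Functional form: depth-wise 1xk then kx1 convolution on (N,C,H,W)."""
    k = max(weight_1xk.shape[-1], weight_1xk.shape[-2])
    if k % 2 == 0:
        raise ValueError("kernel length must be odd")
    y = nn.conv2d(x, weight_1xk, bias_1xk, padding="same", groups=x.shape[1])
    return nn.conv2d(y, weight_kx1, bias_kx1, padding="same", groups=x.shape[1])


class MSCA(nn.Module):
    """A = A0 + A1 + A2 + A3; Attention = Conv1x1(A); Out = Attention ⊙ F."""

    def __init__(self, channels: int, branch_kernels=MSCA_BRANCH_KERNELS):
        super().__init__()
        self.dw5 = nn.Conv2d(channels, channels, 5, groups=channels, padding="same")
        self.branches = nn.ModuleList([SeparableBranch(channels, k) for k in branch_kernels])
        self.proj = nn.Conv2d(channels, channels, 1)
        # attention starts as a near-identity gate (bias 1): the multiplicative
        # branch then perturbs rather than replaces the features at init
        self.proj.bias.data[:] = 1.0

    def __call__(self, f):
        a0 = self.dw5(f)
        a = a0
        for branch in self.branches:
            a = a + branch(a0)
        attention = self.proj(a)
        return attention * f
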