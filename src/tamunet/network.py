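"""Network assembly: plain U-Net baseline and TAMU-Net with ablation toggles.

The baseline is a four-stage U-Net (widths 64-128-256-512, bottleneck 1024):
per stage two 3x3 conv+BN+ReLU, 2x2 max-pooling between stages,
transposed-convolution upsampling, skip concatenation, and a final 1x1
convolution + sigmoid.  TAMU-Net wraps each encoder stage with MSCA
(skips are taken after MSCA, before pooling), runs ASPP in the bottleneck
after the conv block, and routes skips through the channel transformer
(CCT + reconstruction + CCA gate) before decoder concatenation.  Each of the
three additions is an independent flag, so the ablation variants (TAU-Net,
TMU-Net, AMU-Net) are build-time configurations and all flags off reduces
exactly to the baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .aspp import ASPP, ASPP_RATES
from .channel_transformer import ChannelTransformer
from .msca import MSCA

ENCODER_STAGES = ("encoder1", "encoder2", "encoder3", "encoder4")
DECODER_STAGES = ("decoder4", "decoder3", "decoder2", "decoder1")
STAGE_ORDER = (*ENCODER_STAGES, "bottleneck", *DECODER_STAGES)


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 1
    base_width: int = 64        # doubles per stage: 64-128-256-512, bottleneck 1024
    depth: int = 4
    out_channels: int = 1
    use_msca: bool = False
    use_aspp: bool = False
    use_channel_transformer: bool = False
    aspp_rates: tuple = ASPP_RATES
    cct_layers: int = 4         # L
    cct_heads: int = 4          # N
    patch_size: int = 32        # P (for 256x256 inputs -> 64 tokens per scale)
    seed: int = 0

    def __post_init__(self):
        if self.base_width < 1 or self.depth != 4:
            raise ValueError("invalid model config: base_width >= 1 and depth == 4 required")
        if self.patch_size % 8:
            raise ValueError("patch_size must be divisible by 8")

    @property
    def stage_widths(self):
        return [self.base_width * 2**i for i in range(self.depth)]

    @property
    def bottleneck_width(self):
        return self.base_width * 2**self.depth


class DoubleConv(nn.Module):
    """Two 3x3 conv + BN + ReLU blocks (convs bias-free under BN)."""

    def __init__(self, in_ch, out_ch):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, padding="same", bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding="same", bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def __call__(self, x):
        x = nn.relu(self.bn1(self.conv1(x)))
        return nn.relu(self.bn2(self.conv2(x)))


class SegmentationNet(nn.Module):
    """U-Net / TAMU-Net, assembled according to :class:`ModelConfig`."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        nn.manual_seed(config.seed)
        self.config = config
        widths = config.stage_widths
        bott = config.bottleneck_width

        enc_in = [config.in_channels] + widths[:-1]
        self.encoders = nn.ModuleList([DoubleConv(i, o) for i, o in zip(enc_in, widths)])
        self.mscas = (nn.ModuleList([MSCA(w) for w in widths])
                      if config.use_msca else None)
        self.bottleneck = DoubleConv(widths[-1], bott)
        self.aspp = (ASPP(bott, branch_ch=bott, out_ch=bott, rates=config.aspp_rates)
                     if config.use_aspp else None)
        self.transformer = (
            ChannelTransformer(widths, config.patch_size,
                               n_layers=config.cct_layers, n_heads=config.cct_heads)
            if config.use_channel_transformer else None
        )
        ups, decs = [], []
        up_in = bott
        for w in reversed(widths):
            ups.append(nn.ConvTranspose2d2x(up_in, w))
            decs.append(DoubleConv(2 * w, w))
            up_in = w
        self.upconvs = nn.ModuleList(ups)       # decoder4 .. decoder1
        self.decoders = nn.ModuleList(decs)
        self.head = nn.Conv2d(widths[0], config.out_channels, 1)

    def __call__(self, x, return_activations: bool = False):
        x = nn._as_tensor(x)
        acts = {}
        skips = []
        e = x
        for i, enc in enumerate(self.encoders):
            e = enc(e)
            if self.mscas is not None:
                e = self.mscas[i](e)
            acts[ENCODER_STAGES[i]] = e
            skips.append(e)
            e = nn.max_pool2d(e, 2)
        b = self.bottleneck(e)
        if self.aspp is not None:
            b = self.aspp(b)
        acts["bottleneck"] = b

        if self.transformer is not None:
            skips = self.transformer.transform_skips(skips)

        d = b
        for j, (up, dec) in enumerate(zip(self.upconvs, self.decoders)):
            d_up = up(d)
            s = skips[len(skips) - 1 - j]
            if self.transformer is not None:
                s = self.transformer.gate(len(skips) - 1 - j, s, d_up)
            d = dec(nn.concat([s, d_up], axis=1))
            acts[DECODER_STAGES[j]] = d
        out = nn.sigmoid(self.head(d))
        if return_activations:
            return out, acts
        return out


def build_unet(config: ModelConfig | None = None) -> SegmentationNet:
    """Plain baseline U-Net; all architecture flags must be off."""
    config = config or ModelConfig()
    if config.use_msca or config.use_aspp or config.use_channel_transformer:
        raise ValueError("build_unet requires all architecture flags off")
    return SegmentationNet(config)


def build_tamunet(config: ModelConfig | None = None) -> SegmentationNet:
    """TAMU-Net (default: all three modules on); flags reproduce ablations."""
    if config is None:
        config = ModelConfig(use_msca=True, use_aspp=True, use_channel_transformer=True)
    return SegmentationNet(config)


def count_parameters(model: nn.Module) -> int:
    """Number of trainable scalars."""
    return int(sum(p.data.size for p in model.parameters()))


def parameter_breakdown(model: SegmentationNet) -> dict[str, int]:
    """Per-component trainable parameter counts."""
    out: dict[str, int] = {}
    for name, p in model.named_parameters():
        top = name.split(".")[0]
        out[top] = out.get(top, 0) + p.data.size
    return out


def save_checkpoint(model: SegmentationNet, path) -> None:
    """Single-file weights + embedded config (npz)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    cfg = asdict(model.config)
    cfg["aspp_rates"] = list(cfg["aspp_rates"])
    np.savez_compressed(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> SegmentationNet:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        cfg["aspp_rates"] = tuple(cfg["aspp_rates"])
        model = SegmentationNet(ModelConfig(**cfg))
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
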