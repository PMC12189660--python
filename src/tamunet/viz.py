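"""Layer-wise activation heatmaps and segmentation overlay panels.

Heatmaps capture the nine stage outputs (encoder 1-4, bottleneck,
decoder 4-1), reduce each C×H×W block over channels (mean by default, max
optional), min-max normalize to [0, 1] at the layer's native resolution and
render with a fixed colormap.  Overlay panels show the CT slice, the ground
truth and one panel per model prediction.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from PIL import Image

from . import nn
from .network import STAGE_ORDER


def layer_heatmaps(model, image: np.ndarray, reduction: str = "mean") -> dict[str, np.ndarray]:
    """Nine per-stage heatmaps for one preprocessed slice.

    ``image`` is a (H, W) uint8 slice.  Returns {stage: (h, w) float array in
    [0, 1]} in forward order; a constant activation block yields a uniform
    0.5 map (zero-range normalization guard).  Capture runs in eval mode and
    leaves model state untouched.
    """
    if reduction not in ("mean", "max"):
        raise ValueError(f"unknown reduction {reduction!r}")
    was_training = model.training
    model.eval()
    try:
        x = image.astype(np.float32)[None, None] / 255.0
        with nn.no_grad():
            _, acts = model(x, return_activations=True)
    finally:
        if was_training:
            model.train()
    missing = [s for s in STAGE_ORDER if s not in acts]
    if missing:
        raise RuntimeError(f"activation capture failed for stages: {missing}")
    maps = {}
    for stage in STAGE_ORDER:
        a = acts[stage].numpy()[0]  # (C, h, w)
        r = a.mean(axis=0) if reduction == "mean" else a.max(axis=0)
        lo, hi = r.min(), r.max()
        maps[stage] = ((r - lo) / (hi - lo)) if hi > lo else np.full_like(r, 0.5)
    return maps


def render_heatmaps(maps: dict[str, np.ndarray], out_dir, cmap: str = "jet") -> list[Path]:
    """Write each heatmap as a colormapped PNG at its native resolution."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cm = plt.get_cmap(cmap)
    paths = []
    for stage, m in maps.items():
        rgba = (cm(m) * 255).astype(np.uint8)
        p = out_dir / f"heatmap_{stage}.png"
        Image.fromarray(rgba[..., :3]).save(p)
        paths.append(p)
    return paths


def overlay_panel(image: np.ndarray, truth: np.ndarray,
                  predictions: dict[str, np.ndarray], out_path=None):
    """Side-by-side figure: CT slice, ground truth, one panel per prediction.

    Masks are drawn as red tints over the slice.  Returns the figure.
    """
    for name, m in {"truth": truth, **predictions}.items():
        if np.asarray(m).shape != image.shape:
            raise ValueError(f"mask {name!r} shape {np.asarray(m).shape} != image {image.shape}")
    n_panels = 2 + len(predictions)
    fig, axes = plt.subplots(1, n_panels, figsize=(3 * n_panels, 3))
    axes = np.atleast_1d(axes)

    def tint(ax, title, mask=None):
        ax.imshow(image, cmap="gray", vmin=0, vmax=255)
        if mask is not None:
            overlay = np.zeros((*image.shape, 4), dtype=np.float32)
            overlay[np.asarray(mask) > 0] = (1.0, 0.0, 0.0, 0.4)
            ax.imshow(overlay)
        ax.set_title(title, fontsize=9)
        ax.axis("off")

    tint(axes[0], "CT slice")
    tint(axes[1], "ground truth", truth)
    for ax, (name, mask) in zip(axes[2:], predictions.items()):
        tint(ax, name, mask)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=100)
    return fig
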