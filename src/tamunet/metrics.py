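"""2D pixel-level and 3D voxel/surface-level segmentation metrics.

2D: precision, recall, Dice, per-class IoU (liver and background), MIoU
(mean of the two class IoUs), MPA (mean of per-class pixel accuracies) and
accuracy, all from the pixel confusion counts.  3D: slice predictions are
re-stacked along Z into volumes, then DICE/IOU from voxel overlap,
VOE = 1 - IOU, RVD = (|pred| - |truth|)/|truth| kept signed and reported as
a fraction, and the symmetric surface distances ASD (mean) and MSD
(symmetric Hausdorff) between 6-connectivity surface voxels, Euclidean, in
voxel units by default or mm when spacing is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantoms import LabelVolume


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics2D:
    precision: float
    recall: float
    dice: float
    iou_liver: float
    iou_background: float
    miou: float
    mpa: float
    accuracy: float


@dataclass(frozen=True)
class Metrics3D:
    dice3d: float
    iou3d: float
    voe: float
    rvd: float
    asd: float
    msd: float


def _check_binary(arr, name):
    a = np.asarray(arr)
    if not np.isin(np.unique(a), [0, 1]).all():
        raise ValueError(f"{name} must be binary {{0,1}}")
    return a.astype(bool)


def confusion_from_masks(pred, truth) -> ConfusionCounts:
    p = _check_binary(pred, "pred")
    t = _check_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num, den, empty_value=1.0):
    """num/den with the degenerate-denominator convention: if both the
    prediction and the reference contributing to ``den`` are empty the score
    is 1 (perfect agreement on absence); this is applied by the callers which
    pass the appropriate ``empty_value``."""
    return num / den if den > 0 else empty_value


def metrics2d(counts_or_pred, truth=None) -> Metrics2D:
    """Compute the eight 2D scores from a ConfusionCounts or a mask pair."""
    if isinstance(counts_or_pred, ConfusionCounts):
        c = counts_or_pred
    else:
        c = confusion_from_masks(counts_or_pred, truth)
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    precision = _ratio(tp, tp + fp, 1.0 if fn == 0 else 0.0)
    recall = _ratio(tp, tp + fn, 1.0 if fp == 0 else 0.0)
    dice = _ratio(2 * tp, 2 * tp + fp + fn)
    iou_l = _ratio(tp, tp + fp + fn)
    iou_g = _ratio(tn, tn + fp + fn)
    miou = (iou_l + iou_g) / 2.0
    acc_l = _ratio(tp, tp + fn, 1.0 if fp == 0 else 0.0)
    acc_g = _ratio(tn, tn + fp, 1.0 if fn == 0 else 0.0)
    mpa = (acc_l + acc_g) / 2.0
    accuracy = _ratio(tp + tn, c.total)
    return Metrics2D(precision, recall, dice, iou_l, iou_g, miou, mpa, accuracy)


def miou_from_per_class(iou_liver: float, iou_background: float) -> float:
    """MIoU for the two-class task: the mean of the class IoUs."""
    return (iou_liver + iou_background) / 2.0


def dice_from_iou(iou: float) -> float:
    """The Dice-IoU bijection, Dice = 2*IoU / (1 + IoU)."""
    return 2.0 * iou / (1.0 + iou)


def voe_from_iou(iou: float) -> float:
    """Volume overlap error, the complement of volumetric IoU."""
    return 1.0 - iou


def stack_to_volume(slice_masks, case_id: str,
                    spacing=(1.0, 1.0, 1.0)) -> LabelVolume:
    """Assemble (mask, z) slice predictions into a LabelVolume in Z order.

    Requires complete and unique Z coverage 0..Z-1; input order is irrelevant.
    """
    items = sorted(slice_masks, key=lambda mz: mz[1])
    zs = [z for _, z in items]
    if len(set(zs)) != len(zs):
        raise ValueError(f"duplicate Z indices for case {case_id}")
    if zs != list(range(len(zs))):
        missing = sorted(set(range(max(zs) + 1)) - set(zs))
        raise ValueError(f"missing Z slices {missing} for case {case_id}")
    vol = np.stack([np.asarray(m, dtype=np.uint8) for m, _ in items], axis=0)
    return LabelVolume(vol, tuple(spacing), case_id)


def overlap3d(pred: LabelVolume, truth: LabelVolume):
    """(dice3d, iou3d, voe, rvd) from voxel overlap."""
    p = pred.voxels.astype(bool)
    t = truth.voxels.astype(bool)
    if p.shape != t.shape:
        raise ValueError("volume shape mismatch")
    n_t = int(t.sum())
    if n_t == 0:
        raise ValueError("RVD undefined for empty ground truth")
    n_p = int(p.sum())
    inter = int(np.count_nonzero(p & t))
    union = int(np.count_nonzero(p | t))
    dice3d = _ratio(2 * inter, n_p + n_t)
    iou3d = _ratio(inter, union)
    rvd = (n_p - n_t) / n_t
    return dice3d, iou3d, voe_from_iou(iou3d), rvd


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one face-adjacent (6-connectivity)
    background neighbour; voxels at the array border count as surface."""
    m = np.asarray(mask, dtype=bool)
    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(m, structure=struct, border_value=0)
    return m & ~eroded


def surface_distances(pred: LabelVolume, truth: LabelVolume,
                      use_spacing: bool = False) -> tuple[float, float]:
    """(ASD, MSD) between the two mask surfaces.

    Distances are Euclidean nearest-surface distances, in voxel units by
    default or in mm when ``use_spacing`` is set.  ASD sums the directed
    nearest distances both ways and divides by the total surface voxel
    count; MSD is the symmetric Hausdorff maximum.
    """
    p = pred.voxels.astype(bool)
    t = truth.voxels.astype(bool)
    if p.shape != t.shape:
        raise ValueError("volume shape mismatch")
    if not p.any() or not t.any():
        raise ValueError("surface distance undefined for an empty mask")
    sp = surface_voxels(p)
    st = surface_voxels(t)
    sampling = pred.spacing if use_spacing else (1.0, 1.0, 1.0)
    # distance from every voxel to the nearest surface voxel of the other mask
    d_to_t = ndimage.distance_transform_edt(~st, sampling=sampling)
    d_to_p = ndimage.distance_transform_edt(~sp, sampling=sampling)
    dists_p = d_to_t[sp]
    dists_t = d_to_p[st]
    asd = (dists_p.sum() + dists_t.sum()) / (sp.sum() + st.sum())
    msd = max(dists_p.max(), dists_t.max())
    return float(asd), float(msd)


def metrics3d(pred: LabelVolume, truth: LabelVolume,
              use_spacing: bool = False) -> Metrics3D:
    dice3d, iou3d, voe, rvd = overlap3d(pred, truth)
    asd, msd = surface_distances(pred, truth, use_spacing=use_spacing)
    return Metrics3D(dice3d, iou3d, voe, rvd, asd, msd)
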