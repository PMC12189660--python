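"""Slice-wise CT preprocessing: HU windowing, resizing, case-wise splitting,
liver-free-slice filtering and online augmentation.

The pipeline windows raw Hounsfield values to [-400, 400], maps them linearly
to 8-bit, resizes slices to the model input size (bilinear for images,
nearest for masks), splits *cases* 8:1:1 into train/val/test so no slices of
one scan leak across subsets, drops liver-free slices from the training set
only, and applies random rotation (±15°) / scaling (0.9–1.1) per load during
training only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

HU_WINDOW = (-400.0, 400.0)
TARGET_SIZE = 256
ROTATION_DEG = 15.0
SCALE_RANGE = (0.9, 1.1)
SPLIT_RATIO = (8, 1, 1)


@dataclass
class SliceSample:
    """One preprocessed 2D training example with provenance."""

    image: np.ndarray  # (H, W) uint8
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    case_id: str
    z: int

    def validate(self) -> "SliceSample":
        if self.image.shape != self.mask.shape:
            raise ValueError("image/mask shape mismatch")
        if self.image.dtype != np.uint8:
            raise ValueError("image must be uint8")
        if not np.isin(np.unique(self.mask), [0, 1]).all():
            raise ValueError("mask must be binary {0, 1}")
        return self


@dataclass
class SplitManifest:
    """Case-level train/val/test assignment, per source dataset."""

    train: dict[str, list[str]]
    val: dict[str, list[str]]
    test: dict[str, list[str]]
    ratio: tuple[int, int, int]
    seed: int

    def cases(self, role: str) -> list[str]:
        part = getattr(self, role)
        return [c for src in sorted(part) for c in part[src]]

    def role_of(self, case_id: str) -> str:
        for role in ("train", "val", "test"):
            if case_id in self.cases(role):
                return role
        raise KeyError(case_id)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"train": self.train, "val": self.val, "test": self.test,
                       "ratio": list(self.ratio), "seed": self.seed}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SplitManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["train"], d["val"], d["test"], tuple(d["ratio"]), d["seed"])


def clip_scale_hu(raw_slice: np.ndarray, window=HU_WINDOW) -> np.ndarray:
    """Window HU to ``window`` and map linearly to uint8 [0, 255].

    Rounding of the half-way point (e.g. 0 HU -> 127.5) is half-away-from-
    zero, so 0 HU maps to 128.
    """
    raw = np.asarray(raw_slice, dtype=np.float64)
    if not np.all(np.isfinite(raw)):
        raise ValueError("HU input contains non-finite values")
    lo, hi = window
    v = 255.0 * (np.clip(raw, lo, hi) - lo) / (hi - lo)
    return np.floor(v + 0.5).astype(np.uint8)  # values are >= 0


def _resize_bilinear(img: np.ndarray, target: int) -> np.ndarray:
    from .nn import _interp_matrix  # same align_corners=False convention as the model

    Ah = _interp_matrix(img.shape[0], target)
    Aw = _interp_matrix(img.shape[1], target)
    return Ah @ img.astype(np.float64) @ Aw.T


def _resize_nearest(mask: np.ndarray, target: int) -> np.ndarray:
    h, w = mask.shape
    ri = np.minimum((np.arange(target) + 0.5) * h / target, h - 1).astype(int)
    ci = np.minimum((np.arange(target) + 0.5) * w / target, w - 1).astype(int)
    return mask[np.ix_(ri, ci)]


def resize_slice(image: np.ndarray, mask: np.ndarray, case_id: str = "", z: int = 0,
                 target: int = TARGET_SIZE) -> SliceSample:
    """Resize an 8-bit image (bilinear) and its mask (nearest, re-binarized)."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.size == 0 or mask.size == 0:
        raise ValueError("empty input slice")
    if image.shape != mask.shape:
        raise ValueError("image/mask shape mismatch")
    if image.shape == (target, target):
        img_out = image.astype(np.uint8)
    else:
        img_out = np.clip(np.round(_resize_bilinear(image, target)), 0, 255).astype(np.uint8)
    mask_out = (_resize_nearest(mask, target) > 0).astype(np.uint8)
    return SliceSample(img_out, mask_out, case_id, z).validate()


def split_cases(case_ids_per_source: dict[str, list[str]],
                ratio: tuple[int, int, int] = SPLIT_RATIO,
                seed: int = 0) -> SplitManifest:
    """Case-wise split at ``ratio`` (default 8:1:1) within each source.

    Per source with n cases: n_train = floor(0.8 n), n_val = floor(0.1 n),
    and the remainder goes to test — the rule that maps 131 cases to
    (104, 13, 14) and 20 cases to (16, 2, 2).  Assignment of which cases land
    where is a seeded shuffle; membership never crosses sources.
    """
    total = sum(ratio)
    train, val, test = {}, {}, {}
    rng = np.random.default_rng(seed)
    for src in sorted(case_ids_per_source):
        ids = list(case_ids_per_source[src])
        n = len(ids)
        if n < 3:
            raise ValueError(f"source {src!r} has {n} cases; need >= 3 to split")
        order = rng.permutation(n)
        ids = [ids[i] for i in order]
        n_train = int(np.floor(ratio[0] / total * n))
        n_val = int(np.floor(ratio[1] / total * n))
        train[src] = sorted(ids[:n_train])
        val[src] = sorted(ids[n_train:n_train + n_val])
        test[src] = sorted(ids[n_train + n_val:])
    return SplitManifest(train, val, test, tuple(ratio), seed)


def split_counts(n: int, ratio=SPLIT_RATIO) -> tuple[int, int, int]:
    """(n_train, n_val, n_test) under the floor/floor/remainder rule."""
    total = sum(ratio)
    n_train = int(np.floor(ratio[0] / total * n))
    n_val = int(np.floor(ratio[1] / total * n))
    return n_train, n_val, n - n_train - n_val


def drop_liver_free_slices(samples: list[SliceSample], split_role: str) -> list[SliceSample]:
    """Drop slices whose mask is empty — training set only.

    Validation and test sets pass through unchanged so evaluation covers the
    liver-free slices a scanner actually produces.
    """
    if split_role != "train":
        return list(samples)
    return [s for s in samples if s.mask.sum() > 0]


def augment_pair(image: np.ndarray, mask: np.ndarray,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One random rotation (±15°) + scaling (0.9–1.1) draw, applied identically
    to image (bilinear) and mask (nearest, re-binarized).  Drawn fresh per
    call: the same slice sees a different variant at every load.  Fill value
    is 0 (air after windowing) for both."""
    angle = rng.uniform(-ROTATION_DEG, ROTATION_DEG)
    scale = rng.uniform(*SCALE_RANGE)
    h, w = image.shape
    theta = np.deg2rad(angle)
    # output->input map: rotate by -angle and divide by scale, about the centre
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]]) / scale
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - rot @ center
    img_out = ndimage.affine_transform(image.astype(np.float32), rot, offset=offset,
                                       order=1, mode="constant", cval=0.0)
    mask_out = ndimage.affine_transform(mask.astype(np.uint8), rot, offset=offset,
                                        order=0, mode="constant", cval=0)
    img_out = np.clip(np.round(img_out), 0, 255).astype(np.uint8)
    return img_out, (mask_out > 0).astype(np.uint8)


def preprocess_volume(vol, lab, target: int = TARGET_SIZE) -> list[SliceSample]:
    """Window + resize every slice of a phantom/CT volume."""
    from .phantoms import volume_to_slices

    out = []
    for raw, mask, z in volume_to_slices(vol, lab):
        img8 = clip_scale_hu(raw)
        out.append(resize_slice(img8, mask, case_id=vol.case_id, z=z, target=target))
    return out
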