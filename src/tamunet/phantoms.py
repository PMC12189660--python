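"""Synthetic abdominal CT phantoms for liver segmentation.

Each phantom is a 3D Hounsfield-unit volume containing a lobulated
ellipsoidal "liver" (HU drawn around the parenchymal 40-70 HU band), a
configurable number of distractor organs whose intensities overlap the liver
band, sparse air/bone extremes, additive Gaussian noise, and a guaranteed
liver-free band of slices at the top and bottom of the stack.  The paired
binary label volume marks liver voxels.  All randomness flows from a single
seed, so regeneration is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic CT case.

    Lengths are in millimetres; intensities in Hounsfield units (HU).
    ``lobulation_amplitude`` perturbs the liver boundary radially as a
    fraction of the local ellipsoid radius.  ``liver_free_fraction`` of the
    axial slices (split between top and bottom) is guaranteed liver-free,
    which the training-set slice filter later exercises.
    """

    volume_shape: tuple[int, int, int] = (64, 128, 128)  # (Z, Y, X) voxels
    spacing: tuple[float, float, float] = (2.5, 1.5, 1.5)  # mm per axis
    liver_semiaxes: tuple[float, float, float] = (55.0, 65.0, 75.0)  # mm (z,y,x)
    liver_center: tuple[float, float, float] | None = None  # mm; None = volume centre
    lobulation_amplitude: float = 0.12
    liver_hu_mean: float = 55.0
    liver_hu_sd: float = 6.0
    background_hu_mean: float = 10.0
    background_hu_sd: float = 12.0
    distractor_count: int = 3
    noise_sd: float = 8.0
    liver_free_fraction: float = 0.15
    seed: int = 0
    case_id: str = ""

    def __post_init__(self):
        if any(s < 0 for s in self.liver_semiaxes):
            raise ValueError("liver semiaxes must be >= 0")
        if not 0 <= self.liver_free_fraction < 1:
            raise ValueError("liver_free_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")


@dataclass
class CTVolume:
    """3D HU scalar field with voxel spacing (mm) and case identity."""

    voxels: np.ndarray  # (Z, Y, X) float32, HU
    spacing: tuple[float, float, float]
    case_id: str

    def __post_init__(self):
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("CT volume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")


@dataclass
class LabelVolume:
    """Binary liver mask paired with a :class:`CTVolume`."""

    voxels: np.ndarray  # (Z, Y, X) uint8 in {0, 1}
    spacing: tuple[float, float, float]
    case_id: str

    def __post_init__(self):
        vals = np.unique(self.voxels)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("label volume must be binary {0, 1}")


def default_phantom_config(volume_shape=(64, 128, 128),
                           spacing=(2.5, 1.5, 1.5),
                           seed: int = 0, case_id: str = "",
                           **overrides) -> PhantomConfig:
    """A PhantomConfig with liver semiaxes scaled to the volume extent
    (30/33/38 % of the Z/Y/X extent), so phantoms of any size carry the same
    anatomy-to-field-of-view proportions."""
    extent = tuple(n * s for n, s in zip(volume_shape, spacing))
    semiaxes = (0.30 * extent[0], 0.33 * extent[1], 0.38 * extent[2])
    return PhantomConfig(volume_shape=tuple(volume_shape), spacing=tuple(spacing),
                         liver_semiaxes=overrides.pop("liver_semiaxes", semiaxes),
                         seed=seed, case_id=case_id, **overrides)


def _smooth_field(shape, rng, coarse=6):
    """Low-frequency random field in [-1, 1], via trilinear zoom of a coarse grid."""
    grid = rng.standard_normal((coarse, coarse, coarse))
    zoom = [s / coarse for s in shape]
    f = ndimage.zoom(grid, zoom, order=1, mode="nearest", grid_mode=True)
    m = np.abs(f).max()
    return (f / m if m > 0 else f).astype(np.float32)


def _ellipsoid_rho(shape, spacing, center_mm, semiaxes_mm):
    """Normalized radius field rho(x) = ||(x - c) / a||; rho <= 1 inside."""
    axes = [((np.arange(n, dtype=np.float32) * sp - cm) / a) ** 2
            for n, sp, cm, a in zip(shape, spacing, center_mm, semiaxes_mm)]
    rho2 = (axes[0][:, None, None] + axes[1][None, :, None]
            + axes[2][None, None, :])
    return np.sqrt(rho2)


def make_phantom_volume(config: PhantomConfig) -> tuple[CTVolume, LabelVolume]:
    """Generate one (CT, label) phantom pair.

    The liver mask is an ellipsoid indicator perturbed radially by a smoothed
    random field; liver HU are drawn around ``liver_hu_mean``; distractor
    blobs share the liver HU band but never overlap the liver; the top/bottom
    ``liver_free_fraction`` slice band contains no liver.  Raises
    ``ValueError`` if the liver (with lobulation margin) cannot fit between
    the liver-free bands.
    """
    rng = np.random.default_rng(config.seed)
    Z, Y, X = config.volume_shape
    sp = config.spacing
    extent_mm = (Z * sp[0], Y * sp[1], X * sp[2])
    center = config.liver_center or tuple(e / 2 for e in extent_mm)
    case_id = config.case_id or f"phantom-{config.seed:04d}"

    band = int(math.ceil(config.liver_free_fraction * Z / 2))
    a_margin = [s * (1 + config.lobulation_amplitude) for s in config.liver_semiaxes]
    empty_liver = all(s == 0 for s in config.liver_semiaxes)
    if not empty_liver:
        lo_mm = band * sp[0]
        hi_mm = (Z - band) * sp[0]
        if center[0] - a_margin[0] < lo_mm or center[0] + a_margin[0] > hi_mm:
            raise ValueError(
                f"liver (z extent ±{a_margin[0]:.1f} mm around {center[0]:.1f} mm) "
                f"does not fit inside the liver-permitted band [{lo_mm:.1f}, {hi_mm:.1f}] mm"
            )
        for ax in (1, 2):
            if center[ax] - a_margin[ax] < 0 or center[ax] + a_margin[ax] > extent_mm[ax]:
                raise ValueError("liver does not fit inside the volume")

    # liver mask: lobulated ellipsoid
    if empty_liver:
        liver = np.zeros(config.volume_shape, dtype=bool)
    else:
        rho = _ellipsoid_rho(config.volume_shape, sp, center, config.liver_semiaxes)
        lob = _smooth_field(config.volume_shape, rng) if config.lobulation_amplitude > 0 \
            else np.zeros(config.volume_shape, dtype=np.float32)
        liver = rho <= 1.0 + config.lobulation_amplitude * lob
        if band > 0:
            liver[:band] = False
            liver[Z - band:] = False
    # rng state must not depend on whether lobulation was sampled
    if empty_liver:
        rng.standard_normal((6, 6, 6))
    elif config.lobulation_amplitude == 0:
        rng.standard_normal((6, 6, 6))

    hu = rng.normal(config.background_hu_mean, config.background_hu_sd,
                    size=config.volume_shape).astype(np.float32)

    # distractor organs: ellipsoids sharing the liver HU band, clipped away
    # from the liver mask so labels stay clean
    semi_cap = np.array([0.45 * e for e in extent_mm])
    for _ in range(config.distractor_count):
        semi = np.minimum(rng.uniform(10.0, 30.0, size=3), semi_cap)
        c = [rng.uniform(a, e - a) for a, e in zip(semi, extent_mm)]
        blob = _ellipsoid_rho(config.volume_shape, sp, c, semi) <= 1.0
        blob &= ~liver
        hu[blob] = rng.normal(config.liver_hu_mean, config.liver_hu_sd, size=int(blob.sum()))

    # air and bone extremes
    for hu_val, lo_r, hi_r in ((-950.0, 5.0, 15.0), (700.0, 4.0, 10.0)):
        for _ in range(2):
            semi = np.minimum(rng.uniform(lo_r, hi_r, size=3), semi_cap)
            c = [rng.uniform(a, e - a) for a, e in zip(semi, extent_mm)]
            blob = _ellipsoid_rho(config.volume_shape, sp, c, semi) <= 1.0
            blob &= ~liver
            hu[blob] = hu_val

    if liver.any():
        hu[liver] = rng.normal(config.liver_hu_mean, config.liver_hu_sd,
                               size=int(liver.sum()))
    if config.noise_sd > 0:
        hu += rng.normal(0.0, config.noise_sd, size=config.volume_shape).astype(np.float32)

    vol = CTVolume(hu.astype(np.float32), sp, case_id)
    lab = LabelVolume(liver.astype(np.uint8), sp, case_id)
    return vol, lab


def volume_to_slices(vol: CTVolume, lab: LabelVolume):
    """Emit (raw HU slice, binary mask, z) in ascending Z.

    Z indices are preserved so slice-wise predictions can later be re-stacked
    into volumes for the 3D metrics.
    """
    if vol.voxels.shape != lab.voxels.shape:
        raise ValueError(f"volume {vol.voxels.shape} / label {lab.voxels.shape} shape mismatch")
    return [(vol.voxels[z], lab.voxels[z], z) for z in range(vol.voxels.shape[0])]


def write_volume_nifti(vol: CTVolume, lab: LabelVolume, out_dir) -> tuple[Path, Path]:
    """Write a phantom pair as NIfTI (.nii.gz); returns the two paths."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # nibabel is (X, Y, Z) by convention; affine carries spacing
    aff = np.diag([vol.spacing[2], vol.spacing[1], vol.spacing[0], 1.0])
    img_p = out_dir / f"{vol.case_id}_ct.nii.gz"
    lab_p = out_dir / f"{vol.case_id}_mask.nii.gz"
    nib.save(nib.Nifti1Image(vol.voxels.T.astype(np.float32), aff), img_p)
    nib.save(nib.Nifti1Image(lab.voxels.T.astype(np.uint8), aff), lab_p)
    return img_p, lab_p


def read_volume_nifti(ct_path, mask_path) -> tuple[CTVolume, LabelVolume]:
    import nibabel as nib

    img = nib.load(str(ct_path))
    msk = nib.load(str(mask_path))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    case_id = Path(ct_path).name.replace("_ct.nii.gz", "")
    vol = CTVolume(np.asarray(img.dataobj).T.astype(np.float32), spacing, case_id)
    lab = LabelVolume((np.asarray(msk.dataobj).T > 0).astype(np.uint8), spacing, case_id)
    return vol, lab


def write_dataset(samples, root_path, image_format: str = "png") -> pd.DataFrame:
    """Write preprocessed 8-bit slice samples to disk and return the manifest.

    ``samples`` yields objects with .image (uint8 HxW), .mask ({0,1} HxW),
    .case_id and .z (see preprocessing.SliceSample).  Images go to
    ``images/`` as PNG (default, lossless) or JPG; masks always to ``masks/``
    as PNG with on-disk values {0, 255}.  The manifest (one row per slice:
    case_id, z, image_path, mask_path) is also saved as manifest.csv.
    """
    if image_format not in ("png", "jpg"):
        raise ValueError(f"unsupported image format {image_format!r}")
    root = Path(root_path)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        stem = f"{s.case_id}_z{s.z:04d}"
        img_p = root / "images" / f"{stem}.{image_format}"
        mask_p = root / "masks" / f"{stem}.png"
        Image.fromarray(np.asarray(s.image, dtype=np.uint8), mode="L").save(img_p)
        Image.fromarray((np.asarray(s.mask, dtype=np.uint8) * 255), mode="L").save(mask_p)
        rows.append({"case_id": s.case_id, "z": s.z,
                     "image_path": str(img_p), "mask_path": str(mask_p)})
    manifest = pd.DataFrame(rows).sort_values(["case_id", "z"]).reset_index(drop=True)
    manifest.to_csv(root / "manifest.csv", index=False)
    return manifest
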