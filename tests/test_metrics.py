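"""2D/3D metric battery: confusion tallies, printed-row identities, stacking,
overlap scores, and surface distances against the all-pairs brute force."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tamunet.metrics import (ConfusionCounts, confusion_from_masks,
                             dice_from_iou, metrics2d, metrics3d,
                             miou_from_per_class, overlap3d, stack_to_volume,
                             surface_distances, surface_voxels, voe_from_iou)
from tamunet.phantoms import LabelVolume


def _vol(arr, spacing=(1.0, 1.0, 1.0)):
    return LabelVolume(np.asarray(arr, dtype=np.uint8), spacing, "t")


class TestConfusion:
    def test_all_ones(self):
        ones = np.ones((4, 4), dtype=np.uint8)
        c = confusion_from_masks(ones, ones)
        assert (c.tp, c.fp, c.fn, c.tn) == (16, 0, 0, 0)

    def test_complement(self):
        t = np.zeros((4, 4), dtype=np.uint8)
        t[:2] = 1
        c = confusion_from_masks(1 - t, t)
        assert c.tp == 0 and c.tn == 0 and c.fp == 8 and c.fn == 8

    def test_matches_per_pixel_tally(self, rng):
        p = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        t = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        c = confusion_from_masks(p, t)
        tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for i in range(8):
            for j in range(8):
                key = {(1, 1): "tp", (1, 0): "fp", (0, 1): "fn", (0, 0): "tn"}[(p[i, j], t[i, j])]
                tally[key] += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tally["tp"], tally["fp"], tally["fn"], tally["tn"])
        assert c.total == 64

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_masks(np.array([[2]]), np.array([[1]]))


class TestMetrics2D:
    def test_identical_masks_all_ones(self, rng):
        m = (rng.random((16, 16)) > 0.4).astype(np.uint8)
        s = metrics2d(m, m)
        for v in vars(s).values():
            assert v == 1.0

    def test_hand_worked_counts(self):
        s = metrics2d(ConfusionCounts(tp=2, fp=1, fn=1, tn=12))
        assert s.precision == pytest.approx(2 / 3)
        assert s.recall == pytest.approx(2 / 3)
        assert s.dice == pytest.approx(2 / 3)
        assert s.iou_liver == pytest.approx(1 / 2)

    def test_miou_of_reported_per_class_ious(self):
        # per-class IoUs (liver, background) -> their mean
        assert miou_from_per_class(0.9315, 0.9983) == pytest.approx(0.9649, abs=5e-5)

    def test_dice_iou_bijection_on_random_masks(self, rng):
        p = (rng.random((12, 12)) > 0.5).astype(np.uint8)
        t = (rng.random((12, 12)) > 0.3).astype(np.uint8)
        s = metrics2d(p, t)
        assert s.dice == pytest.approx(dice_from_iou(s.iou_liver), abs=1e-12)


class TestStackToVolume:
    def test_round_trip(self, small_phantom):
        _, lab = small_phantom
        slices = [(lab.voxels[z], z) for z in range(lab.voxels.shape[0])]
        out = stack_to_volume(slices, lab.case_id, lab.spacing)
        assert np.array_equal(out.voxels, lab.voxels)

    def test_order_invariance(self, small_phantom):
        _, lab = small_phantom
        slices = [(lab.voxels[z], z) for z in range(lab.voxels.shape[0])][::-1]
        out = stack_to_volume(slices, lab.case_id)
        assert np.array_equal(out.voxels, lab.voxels)

    def test_missing_slice_rejected(self):
        slices = [(np.zeros((4, 4)), z) for z in (0, 1, 3)]
        with pytest.raises(ValueError, match="missing"):
            stack_to_volume(slices, "c")

    def test_duplicate_slice_rejected(self):
        slices = [(np.zeros((4, 4)), z) for z in (0, 1, 1)]
        with pytest.raises(ValueError, match="duplicate"):
            stack_to_volume(slices, "c")


class TestOverlap3D:
    def test_identical_volumes(self, small_phantom):
        _, lab = small_phantom
        assert overlap3d(lab, lab) == (1.0, 1.0, 0.0, 0.0)

    def test_voe_complements_iou_printed_row(self):
        # the published 3D row: IOU 0.9446 pairs with VOE 0.0554
        assert voe_from_iou(0.9446) == pytest.approx(0.0554, abs=1e-12)

    def test_dice_from_iou_printed_row(self):
        # ... and with DICE 0.9715 via 2*IOU/(1+IOU)
        assert dice_from_iou(0.9446) == pytest.approx(0.9715, abs=5e-5)

    def test_identities_on_synthetic_volumes(self, rng):
        a = _vol(rng.random((6, 8, 8)) > 0.5)
        b = _vol(rng.random((6, 8, 8)) > 0.4)
        dice3d, iou3d, voe, rvd = overlap3d(a, b)
        assert voe == pytest.approx(1.0 - iou3d, abs=1e-12)
        assert dice3d == pytest.approx(dice_from_iou(iou3d), abs=1e-12)
        assert rvd == pytest.approx((int(a.voxels.sum()) - int(b.voxels.sum()))
                                    / int(b.voxels.sum()))

    def test_empty_truth_rejected(self):
        a = _vol(np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            overlap3d(a, _vol(np.zeros((2, 2, 2))))


def _brute_force_distances(pa, pb, spacing):
    """All-pairs Euclidean distances between surface voxel sets."""
    sa = np.argwhere(surface_voxels(pa)) * np.asarray(spacing)
    sb = np.argwhere(surface_voxels(pb)) * np.asarray(spacing)
    d = np.sqrt(((sa[:, None] - sb[None]) ** 2).sum(-1))
    da, db = d.min(axis=1), d.min(axis=0)
    asd = (da.sum() + db.sum()) / (len(sa) + len(sb))
    return asd, max(da.max(), db.max())


class TestSurfaceDistances:
    def test_identical_masks_zero(self, small_phantom):
        _, lab = small_phantom
        assert surface_distances(lab, lab) == (0.0, 0.0)

    def test_single_voxels_three_apart(self):
        a = np.zeros((7, 7, 7)); a[3, 3, 1] = 1
        b = np.zeros((7, 7, 7)); b[3, 3, 4] = 1
        asd, msd = surface_distances(_vol(a), _vol(b))
        assert asd == pytest.approx(3.0) and msd == pytest.approx(3.0)

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 500))
    def test_matches_all_pairs_brute_force(self, seed):
        r = np.random.default_rng(seed)
        a = (r.random((8, 10, 10)) > 0.6)
        b = (r.random((8, 10, 10)) > 0.6)
        if not (a.any() and b.any()):
            return
        asd, msd = surface_distances(_vol(a), _vol(b))
        basd, bmsd = _brute_force_distances(a, b, (1.0, 1.0, 1.0))
        assert asd == pytest.approx(basd, abs=1e-9)
        assert msd == pytest.approx(bmsd, abs=1e-9)

    def test_symmetry(self, rng):
        a = _vol(rng.random((6, 8, 8)) > 0.5)
        b = _vol(rng.random((6, 8, 8)) > 0.5)
        assert surface_distances(a, b) == surface_distances(b, a)

    def test_translation_invariance(self):
        base = np.zeros((10, 10, 10)); base[2:5, 2:5, 2:5] = 1
        other = np.zeros((10, 10, 10)); other[3:6, 2:5, 2:5] = 1
        d1 = surface_distances(_vol(base), _vol(other))
        d2 = surface_distances(_vol(np.roll(base, 3, axis=2)),
                               _vol(np.roll(other, 3, axis=2)))
        assert d1 == pytest.approx(d2)

    def test_spacing_scales_distances(self):
        a = np.zeros((7, 7, 7)); a[3, 3, 1] = 1
        b = np.zeros((7, 7, 7)); b[3, 3, 4] = 1
        asd, msd = surface_distances(_vol(a, spacing=(1.0, 1.0, 2.0)),
                                     _vol(b, spacing=(1.0, 1.0, 2.0)),
                                     use_spacing=True)
        assert asd == pytest.approx(6.0) and msd == pytest.approx(6.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            surface_distances(_vol(np.zeros((3, 3, 3))), _vol(np.ones((3, 3, 3))))


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 1000))
def test_score_ranges_on_random_pairs(seed):
    r = np.random.default_rng(seed)
    p = _vol(r.random((5, 6, 6)) > 0.5)
    t = _vol(r.random((5, 6, 6)) > 0.5)
    if not (p.voxels.any() and t.voxels.any()):
        return
    m = metrics3d(p, t)
    assert 0 <= m.dice3d <= 1 and 0 <= m.iou3d <= 1 and 0 <= m.voe <= 1
    assert m.asd >= 0 and m.msd >= m.asd
    s = metrics2d(p.voxels[0], t.voxels[0])
    for name, v in vars(s).items():
        assert 0 <= v <= 1, name
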