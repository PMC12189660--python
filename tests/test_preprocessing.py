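"""HU windowing, resizing, case-wise splitting, slice filtering and
augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tamunet.preprocessing import (SliceSample, augment_pair, clip_scale_hu,
                                   drop_liver_free_slices, resize_slice,
                                   split_cases, split_counts)


class TestClipScaleHu:
    @pytest.mark.parametrize("hu,expected", [
        (-400.0, 0), (400.0, 255), (-1000.0, 0), (1000.0, 255),
        (0.0, 128),  # 127.5 rounds half-away-from-zero
    ])
    def test_window_endpoints_and_midpoint(self, hu, expected):
        assert clip_scale_hu(np.array([[hu]]))[0, 0] == expected

    def test_constant_slice_stays_constant(self):
        out = clip_scale_hu(np.full((5, 5), 55.0))
        assert len(np.unique(out)) == 1

    def test_monotone_in_hu(self):
        hu = np.linspace(-600, 600, 201)[None]
        out = clip_scale_hu(hu)[0].astype(int)
        assert np.all(np.diff(out) >= 0)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            clip_scale_hu(np.array([[np.nan]]))


class TestResize:
    def test_identity_at_target(self, rng):
        img = rng.integers(0, 256, (256, 256), dtype=np.uint8)
        mask = (rng.random((256, 256)) > 0.5).astype(np.uint8)
        s = resize_slice(img, mask, target=256)
        assert np.array_equal(s.image, img)
        assert np.array_equal(s.mask, mask)

    def test_all_ones_mask_stays_all_ones(self):
        img = np.zeros((512, 512), dtype=np.uint8)
        mask = np.ones((512, 512), dtype=np.uint8)
        s = resize_slice(img, mask, target=256)
        assert s.mask.shape == (256, 256)
        assert s.mask.min() == 1

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            resize_slice(np.zeros((0, 0), dtype=np.uint8),
                         np.zeros((0, 0), dtype=np.uint8))

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 1000), size=st.sampled_from([100, 256, 300, 512]))
    def test_mask_stays_binary(self, seed, size):
        r = np.random.default_rng(seed)
        img = r.integers(0, 256, (size, size), dtype=np.uint8)
        mask = (r.random((size, size)) > 0.5).astype(np.uint8)
        s = resize_slice(img, mask, target=256)
        assert set(np.unique(s.mask)) <= {0, 1}
        assert s.image.shape == s.mask.shape == (256, 256)


class TestSplitCases:
    @pytest.mark.parametrize("n,expected", [
        (131, (104, 13, 14)),  # the large-cohort partition
        (20, (16, 2, 2)),      # the two small-cohort partitions
        (10, (8, 1, 1)),
    ])
    def test_counts(self, n, expected):
        assert split_counts(n) == expected

    def test_case_disjointness_and_coverage(self):
        sources = {f"src{j}": [f"s{j}c{i}" for i in range(17 + 3 * j)] for j in range(3)}
        sm = split_cases(sources, seed=4)
        tr, va, te = (set(sm.cases(r)) for r in ("train", "val", "test"))
        assert tr & va == tr & te == va & te == set()
        assert tr | va | te == {c for ids in sources.values() for c in ids}

    def test_membership_never_crosses_sources(self):
        sources = {"a": [f"a{i}" for i in range(10)], "b": [f"b{i}" for i in range(10)]}
        sm = split_cases(sources, seed=0)
        for part in (sm.train, sm.val, sm.test):
            for src, ids in part.items():
                assert all(c.startswith(src) for c in ids)

    def test_deterministic_given_seed(self):
        src = {"a": [f"c{i}" for i in range(20)]}
        assert split_cases(src, seed=9).train == split_cases(src, seed=9).train

    def test_too_few_cases_raises(self):
        with pytest.raises(ValueError):
            split_cases({"a": ["c0", "c1"]})

    def test_json_round_trip(self, tmp_path):
        sm = split_cases({"a": [f"c{i}" for i in range(10)]}, seed=1)
        p = tmp_path / "split.json"
        sm.to_json(p)
        from tamunet.preprocessing import SplitManifest

        sm2 = SplitManifest.from_json(p)
        assert sm2.train == sm.train and sm2.test == sm.test


def _mk(mask_value, case="c", z=0):
    img = np.zeros((8, 8), dtype=np.uint8)
    mask = np.full((8, 8), mask_value, dtype=np.uint8)
    return SliceSample(img, mask, case, z)


class TestDropLiverFree:
    def test_train_empty_mask_removed(self):
        assert drop_liver_free_slices([_mk(0)], "train") == []

    def test_test_empty_mask_retained(self):
        assert len(drop_liver_free_slices([_mk(0)], "test")) == 1
        assert len(drop_liver_free_slices([_mk(0)], "val")) == 1

    def test_all_liver_slice_retained(self):
        assert len(drop_liver_free_slices([_mk(1)], "train")) == 1

    def test_idempotent(self):
        samples = [_mk(0), _mk(1), _mk(0, z=2)]
        once = drop_liver_free_slices(samples, "train")
        assert drop_liver_free_slices(once, "train") == once


class TestAugmentPair:
    def test_identity_when_rng_degenerate(self, tiny_samples):
        class FixedRng:
            def uniform(self, lo, hi):
                return 0.0 if lo < 0 else 1.0

        s = tiny_samples[len(tiny_samples) // 2]
        img, mask = augment_pair(s.image, s.mask, FixedRng())
        assert np.array_equal(img, s.image)
        assert np.array_equal(mask, s.mask)

    def test_mask_binary_and_shape_stable_many_draws(self, tiny_samples):
        r = np.random.default_rng(0)
        s = tiny_samples[len(tiny_samples) // 2]
        for _ in range(200):
            img, mask = augment_pair(s.image, s.mask, r)
            assert img.shape == s.image.shape
            assert set(np.unique(mask)) <= {0, 1}

    def test_independent_draws_differ(self, tiny_samples):
        s = tiny_samples[len(tiny_samples) // 2]
        a = augment_pair(s.image, s.mask, np.random.default_rng(1))
        b = augment_pair(s.image, s.mask, np.random.default_rng(2))
        assert not np.array_equal(a[0], b[0])
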