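import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hncascade.cascade import (BoundingBox, CropSpec, InputRecipe,
                               assemble_coarse_input, coarse_feed_channel,
                               combined_crop_box, crop, grid_center_box,
                               mask_bbox, paste_back, run_cascade,
                               soft_label_channel)
from hncascade.preprocessing import DilationSpec
from hncascade.unet3d import NetworkSpec, build_network
from hncascade.volume_io import CaseRecord, LabelVolume, Volume3D

from conftest import random_label_volume


def _case(shape=(16, 16, 8), with_prior_fg=True):
    rng = np.random.default_rng(4)
    img = Volume3D(rng.normal(size=shape).astype(np.float32), (1, 1, 2))
    pre = np.zeros(shape, dtype=np.int16)
    if with_prior_fg:
        pre[4:8, 4:8, 2:5] = 1
        pre[10:12, 10:12, 3:5] = 2
    mid = np.roll(pre, (1, 0, 0), axis=(0, 1, 2))
    return CaseRecord("c", img, Volume3D(img.data * 0.5, (1, 1, 2)),
                      LabelVolume(pre, (1, 1, 2)), LabelVolume(mid, (1, 1, 2)))


class TestAssembleInput:
    def test_mid_only_single_channel(self):
        case = _case()
        x = assemble_coarse_input(case, None, InputRecipe.MID_ONLY)
        assert x.shape == (1,) + case.mid_image.shape
        np.testing.assert_array_equal(x[0], case.mid_image.data)

    def test_premask_channel_is_integer_labels(self):
        case = _case()
        x = assemble_coarse_input(case, case.pre_mask_reg, InputRecipe.PREMASK_MID)
        assert x.shape[0] == 2
        assert set(np.unique(x[0])) <= {0.0, 1.0, 2.0}
        np.testing.assert_array_equal(x[1], case.mid_image.data)

    def test_three_channel_order(self):
        case = _case()
        x = assemble_coarse_input(case, case.pre_mask_reg, InputRecipe.PREIMG_PREMASK_MID)
        assert x.shape[0] == 3
        np.testing.assert_array_equal(x[0], case.pre_image_reg.data)
        np.testing.assert_array_equal(x[2], case.mid_image.data)

    def test_missing_prior_rejected(self):
        with pytest.raises(ValueError, match="prior"):
            assemble_coarse_input(_case(), None, InputRecipe.PREMASK_MID)


class TestMaskBbox:
    def test_single_voxel(self):
        m = np.zeros((32, 32, 12), dtype=np.int16)
        m[10, 20, 5] = 2
        box = mask_bbox(m)
        assert box.lo == (10, 20, 5) and box.hi == (11, 21, 6)

    def test_empty_is_none(self):
        assert mask_bbox(np.zeros((4, 4, 4), dtype=np.int16)) is None

    def test_matches_enumeration(self, rng):
        vol = random_label_volume(rng, shape=(13, 11, 9))
        box = mask_bbox(vol)
        coords = np.argwhere(vol.data > 0)
        assert box.lo == tuple(coords.min(axis=0))
        assert box.hi == tuple(coords.max(axis=0) + 1)


class TestCombinedCropBox:
    GRID = (336, 336, 160)
    CROP = CropSpec((256, 256, 96))

    def test_prior_only_fallback_when_coarse_empty(self):
        prior = BoundingBox((160, 160, 70), (176, 176, 90))
        box = combined_crop_box(None, prior, self.CROP, self.GRID)
        assert box.shape == (256, 256, 96)
        assert box.lo == (40, 40, 32)  # centered on the prior box center

    def test_truncated_midpoint_and_face_clamp(self):
        a = BoundingBox((10, 10, 10), (11, 11, 11))
        b = BoundingBox((50, 50, 50), (51, 51, 51))
        box = combined_crop_box(a, b, self.CROP, self.GRID)
        # union [10,51): truncated midpoint 30; 30-128 clamps to 0
        assert box.lo[0] == 0 and box.hi[0] == 256

    def test_both_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            combined_crop_box(None, None, self.CROP, self.GRID)

    @settings(deadline=None, max_examples=100)
    @given(st.tuples(*[st.integers(0, 335) for _ in range(2)]),
           st.tuples(*[st.integers(0, 335) for _ in range(2)]),
           st.integers(0, 159), st.integers(0, 159))
    def test_fuzzed_always_in_bounds_exact_shape(self, xy1, xy2, z1, z2):
        mk = lambda x, y, z: BoundingBox((x, y, z), (x + 1, y + 1, z + 1))
        box = combined_crop_box(mk(xy1[0], xy1[1], z1), mk(xy2[0], xy2[1], z2),
                                self.CROP, self.GRID)
        assert box.shape == self.CROP.crop_shape
        assert all(l >= 0 for l in box.lo)
        assert all(h <= g for h, g in zip(box.hi, self.GRID))


class TestCropPaste:
    def test_roundtrip_identity(self, rng):
        vol = rng.integers(0, 3, (20, 18, 10)).astype(np.int16)
        box = BoundingBox((2, 4, 1), (14, 16, 9))
        back = paste_back(crop(vol, box), box, vol.shape)
        np.testing.assert_array_equal(back[box.slices()], vol[box.slices()])
        outside = back.copy()
        outside[box.slices()] = 0
        assert (outside == 0).all()

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            crop(np.zeros((8, 8, 8)), BoundingBox((0, 0, 4), (4, 4, 12)))

    def test_tumor_voxels_preserved_when_inside_box(self):
        vol = np.zeros((20, 20, 10), dtype=np.int16)
        vol[5:9, 5:9, 3:6] = 1
        box = BoundingBox((2, 2, 1), (14, 14, 9))
        assert (crop(vol, box) == 1).sum() == (vol == 1).sum()


def test_soft_label_channel_matches_argmax_when_confident():
    scores = np.zeros((3, 4, 4, 2), dtype=np.float32)
    scores[2, :2] = 50.0
    scores[1, 2:] = 50.0
    soft = soft_label_channel(scores)
    np.testing.assert_allclose(soft[:2], 2.0, atol=1e-4)
    np.testing.assert_allclose(soft[2:], 1.0, atol=1e-4)


def test_coarse_feed_modes_shapes():
    scores = np.random.default_rng(0).normal(size=(3, 6, 6, 4)).astype(np.float32)
    assert coarse_feed_channel(scores, "soft").shape == (1, 6, 6, 4)
    assert coarse_feed_channel(scores, "labels").shape == (1, 6, 6, 4)
    assert coarse_feed_channel(scores, "onehot").shape == (3, 6, 6, 4)
    with pytest.raises(ValueError):
        coarse_feed_channel(scores, "bogus")


class TestRunCascade:
    def _nets(self):
        coarse = build_network(NetworkSpec(in_channels=2, stage_widths=(4, 8)), seed=0)
        fine = build_network(NetworkSpec(in_channels=2, stage_widths=(4, 8)), seed=1)
        return coarse, fine

    def test_completes_and_labels_valid(self):
        case = _case()
        coarse, fine = self._nets()
        out = run_cascade(case, coarse, fine, InputRecipe.PREMASK_MID,
                          CropSpec((8, 8, 4)), DilationSpec((2, 2, 1)))
        assert out.shape == case.mid_image.shape
        assert set(np.unique(out.data)) <= {0, 1, 2}

    def test_empty_prior_and_coarse_falls_back_to_grid_center(self):
        """An untrained net may predict nothing; the pipeline must finish."""
        case = _case(with_prior_fg=False)
        coarse, fine = self._nets()
        # force an empty coarse prediction by biasing the head to background
        coarse.head.bias.data = np.array([100.0, 0.0, 0.0], dtype=np.float32)
        out = run_cascade(case, coarse, fine, InputRecipe.PREMASK_MID,
                          CropSpec((8, 8, 4)), DilationSpec((2, 2, 1)))
        assert out.shape == case.mid_image.shape

    def test_deterministic_given_weights(self):
        case = _case()
        coarse, fine = self._nets()
        kw = dict(recipe=InputRecipe.PREMASK_MID, crop_spec=CropSpec((8, 8, 4)),
                  dilation=DilationSpec((2, 2, 1)))
        a = run_cascade(case, coarse, fine, **kw)
        b = run_cascade(case, coarse, fine, **kw)
        np.testing.assert_array_equal(a.data, b.data)

    def test_fine_fov_contains_truth_when_shift_small(self):
        """With shift within the dilation radii the crop anchored on the
        dilated prior covers every ground-truth voxel."""
        case = _case()
        from hncascade.preprocessing import dilate_mask
        prior = dilate_mask(case.pre_mask_reg, DilationSpec((2, 2, 1)))
        pb = mask_bbox(prior)
        box = combined_crop_box(None, pb, CropSpec((16, 16, 8)), case.mid_image.shape)
        truth = np.argwhere(case.mid_mask.data > 0)
        assert (truth >= box.lo).all() and (truth < box.hi).all()
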