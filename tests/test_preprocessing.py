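import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hncascade.preprocessing import (DilationSpec, GridSpec, NormalizationSpec,
                                     clip_normalize, cohort_overlap_report,
                                     dilate_mask, overlap_ratio,
                                     resample_to_grid, structuring_element)
from hncascade.volume_io import CaseRecord, LabelVolume, Volume3D

from conftest import random_label_volume


def brute_force_dilate(mask: np.ndarray, selem: np.ndarray) -> np.ndarray:
    """Offset-enumeration oracle: OR of the mask shifted by every element
    offset."""
    r = tuple(s // 2 for s in selem.shape)
    out = np.zeros_like(mask, dtype=bool)
    for dx in range(-r[0], r[0] + 1):
        for dy in range(-r[1], r[1] + 1):
            for dz in range(-r[2], r[2] + 1):
                if not selem[dx + r[0], dy + r[1], dz + r[2]]:
                    continue
                shifted = np.zeros_like(mask, dtype=bool)
                src = tuple(slice(max(0, -d), mask.shape[a] - max(0, d))
                            for a, d in enumerate((dx, dy, dz)))
                dst = tuple(slice(max(0, d), mask.shape[a] - max(0, -d))
                            for a, d in enumerate((dx, dy, dz)))
                shifted[dst] = mask[src]
                out |= shifted
    return out


class TestClipNormalize:
    def test_zscore_mean_sd(self, rng):
        img = Volume3D(rng.normal(50, 10, (12, 12, 8)).astype(np.float32), (1, 1, 2))
        mask = LabelVolume((rng.random((12, 12, 8)) < 0.2).astype(np.int16), (1, 1, 2))
        out = clip_normalize(img, mask)
        assert abs(out.data.mean()) < 1e-5
        assert abs(out.data.std() - 1) < 1e-5

    def test_outlier_outside_region_clipped_to_region_percentile(self, rng):
        data = rng.normal(100, 5, (10, 10, 6))
        mask = np.zeros((10, 10, 6), dtype=np.int16)
        mask[3:7, 3:7, 2:4] = 1
        data[0, 0, 0] = 1e6  # extreme outlier outside the mask region
        region = np.sort(data[mask > 0])
        low, high = np.percentile(region, [0.5, 99.5])
        img = Volume3D(data.astype(np.float32), (1, 1, 1))
        out = clip_normalize(img, LabelVolume(mask, (1, 1, 1)))
        clipped = np.clip(data, low, high)
        expect = (clipped - clipped.mean()) / clipped.std()
        np.testing.assert_allclose(out.data, expect, atol=1e-4)

    def test_constant_image_returns_zeros_with_warning(self):
        img = Volume3D(np.full((6, 6, 4), 5.0, dtype=np.float32), (1, 1, 1))
        mask = LabelVolume(np.ones((6, 6, 4), dtype=np.int16), (1, 1, 1))
        with pytest.warns(UserWarning, match="constant"):
            out = clip_normalize(img, mask)
        assert (out.data == 0).all()

    def test_empty_region_raises(self):
        img = Volume3D(np.ones((6, 6, 4), dtype=np.float32), (1, 1, 1))
        mask = LabelVolume(np.zeros((6, 6, 4), dtype=np.int16), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            clip_normalize(img, mask)

    def test_rank_preserved_on_reapplication(self, rng):
        """Idempotent up to the affine rescale: ordering never changes."""
        img = Volume3D(rng.normal(0, 1, (8, 8, 6)).astype(np.float32), (1, 1, 1))
        spec = NormalizationSpec(region="nonzero_image")
        once = clip_normalize(img, None, spec)
        twice = clip_normalize(once, None, spec)
        order = np.argsort(once.data.ravel(), kind="stable")
        np.testing.assert_array_equal(order, np.argsort(twice.data.ravel(), kind="stable"))


class TestResample:
    def test_identity_on_own_grid(self, small_label):
        grid = GridSpec(small_label.shape, small_label.spacing)
        out = resample_to_grid(small_label, grid)
        np.testing.assert_array_equal(out.data, small_label.data)

    def test_label_value_set_preserved(self, small_label):
        out = resample_to_grid(small_label, GridSpec((9, 7, 5), (1.3, 1.4, 3.1)))
        assert set(np.unique(out.data)) <= {0, 1, 2}

    def test_integer_upsampling_maps_to_blocks(self, rng):
        data = rng.integers(0, 3, (8, 8, 4)).astype(np.int16)
        v = LabelVolume(data, (1, 1, 2))
        out = resample_to_grid(v, GridSpec((16, 16, 8), (0.5, 0.5, 1.0)))
        # index-arithmetic oracle: output voxel j comes from input voxel j//2
        expect = data[np.arange(16) // 2][:, np.arange(16) // 2][:, :, np.arange(8) // 2]
        np.testing.assert_array_equal(out.data, expect)

    def test_downsample_then_upsample_restores_interior(self, rng):
        data = np.zeros((16, 16, 8), dtype=np.int16)
        data[4:12, 4:12, 2:6] = 1
        v = LabelVolume(data, (1.0, 1.0, 2.0))
        down = resample_to_grid(v, GridSpec((8, 8, 4), (2.0, 2.0, 4.0)))
        back = resample_to_grid(down, GridSpec((16, 16, 8), (1.0, 1.0, 2.0)))
        interior = data[5:11, 5:11, 3:5]
        np.testing.assert_array_equal(back.data[5:11, 5:11, 3:5], interior)

    def test_image_output_shape_and_spacing(self, rng):
        v = Volume3D(rng.normal(size=(10, 12, 6)).astype(np.float32), (1, 1, 2))
        out = resample_to_grid(v, GridSpec((20, 20, 10), (0.7, 0.7, 1.5)))
        assert out.shape == (20, 20, 10)
        assert out.spacing == (0.7, 0.7, 1.5)


class TestDilation:
    def test_zero_radii_identity(self, small_label):
        out = dilate_mask(small_label, DilationSpec((0, 0, 0)))
        np.testing.assert_array_equal(out.data, small_label.data)

    def test_single_voxel_ellipsoid_count_matches_enumeration(self):
        data = np.zeros((20, 20, 12), dtype=np.int16)
        data[10, 10, 6] = 1
        out = dilate_mask(LabelVolume(data, (1, 1, 2)), DilationSpec((6, 6, 3)))
        count = 0
        for dx in range(-6, 7):
            for dy in range(-6, 7):
                for dz in range(-3, 4):
                    if (dx / 6) ** 2 + (dy / 6) ** 2 + (dz / 3) ** 2 <= 1 + 1e-12:
                        count += 1
        assert int((out.data == 1).sum()) == count

    @pytest.mark.parametrize("element", ["ellipsoid", "box"])
    def test_matches_offset_enumeration_oracle(self, rng, element):
        spec = DilationSpec((2, 3, 1), element)
        selem = structuring_element(spec)
        for _ in range(6):
            vol = random_label_volume(rng, shape=(14, 12, 9), density=0.05)
            out = dilate_mask(vol, spec)
            for cls in (1, 2):
                oracle = brute_force_dilate(vol.data == cls, selem)
                got = out.data == cls
                # oracle ignores the cross-class collision rule: claimed
                # voxels must still be covered by one of the two classes
                both = oracle & brute_force_dilate(vol.data == (3 - cls), selem)
                np.testing.assert_array_equal(got | both, oracle | (vol.data == cls))

    def test_extensive_and_monotone(self, rng):
        spec = DilationSpec((2, 2, 1))
        a = random_label_volume(rng, shape=(10, 10, 8), density=0.05)
        sub = a.like(np.where(rng.random(a.shape) < 0.5, a.data, 0))
        da, dsub = dilate_mask(a, spec), dilate_mask(sub, spec)
        for cls in (1, 2):
            assert ((a.data == cls) <= (da.data == cls)).all()  # extensive
        # monotone on the pooled foreground
        assert ((dsub.data > 0) <= (da.data > 0)).all()

    def test_original_labels_survive_collisions(self):
        data = np.zeros((12, 12, 6), dtype=np.int16)
        data[4, 6, 3] = 1
        data[8, 6, 3] = 2
        out = dilate_mask(LabelVolume(data, (1, 1, 2)), DilationSpec((4, 4, 2)))
        assert out.data[4, 6, 3] == 1 and out.data[8, 6, 3] == 2
        # single label everywhere
        assert set(np.unique(out.data)) <= {0, 1, 2}


class TestOverlap:
    def _vols(self, mid, dil):
        return (LabelVolume(mid, (1, 1, 2)), LabelVolume(dil, (1, 1, 2)))

    def test_empty_mid_class_undefined(self):
        mid = np.zeros((6, 6, 4), dtype=np.int16)
        dil = np.ones((6, 6, 4), dtype=np.int16)
        m, d = self._vols(mid, dil)
        assert overlap_ratio(m, d, 1) is None

    def test_subset_gives_one(self):
        mid = np.zeros((6, 6, 4), dtype=np.int16)
        mid[2:4, 2:4, 1:3] = 1
        dil = np.zeros((6, 6, 4), dtype=np.int16)
        dil[1:5, 1:5, 0:4] = 1
        m, d = self._vols(mid, dil)
        assert overlap_ratio(m, d, 1) == 1.0

    def test_partial_overlap_counts_voxels(self):
        mid = np.zeros((8, 8, 4), dtype=np.int16)
        mid[0, 0:8, 0] = 1  # 8 voxels
        dil = np.zeros((8, 8, 4), dtype=np.int16)
        dil[0, 0:6, 0] = 1  # covers 6 of them
        m, d = self._vols(mid, dil)
        assert overlap_ratio(m, d, 1) == pytest.approx(0.75)

    def test_cohort_report_excludes_missing_class(self):
        img = Volume3D(np.zeros((8, 8, 4), dtype=np.float32), (1, 1, 2))
        pre = np.zeros((8, 8, 4), dtype=np.int16)
        pre[2:5, 2:5, 1:3] = 1
        mid_a = pre.copy()          # GTVp present, no GTVn
        mid_b = np.zeros_like(pre)  # nothing at mid
        mid_b[3, 3, 1] = 2
        cases = [
            CaseRecord("a", img, img, LabelVolume(pre, (1, 1, 2)),
                       LabelVolume(mid_a, (1, 1, 2))),
            CaseRecord("b", img, img, LabelVolume(pre, (1, 1, 2)),
                       LabelVolume(mid_b, (1, 1, 2))),
        ]
        rep = cohort_overlap_report(cases, DilationSpec((1, 1, 1)))
        mean_row = rep[rep.case_id == "mean"].iloc[0]
        assert mean_row["gtvp"] == 1.0  # case b excluded (no GTVp at mid)
        assert rep[rep.case_id == "b"]["gtvp"].isna().all()

    def test_single_case_mean_equals_case_value(self):
        img = Volume3D(np.zeros((8, 8, 4), dtype=np.float32), (1, 1, 2))
        pre = np.zeros((8, 8, 4), dtype=np.int16)
        pre[2:5, 2:5, 1:3] = 1
        mid = np.zeros_like(pre)
        mid[2:6, 2:5, 1:3] = 1
        case = CaseRecord("a", img, img, LabelVolume(pre, (1, 1, 2)),
                          LabelVolume(mid, (1, 1, 2)))
        rep = cohort_overlap_report([case], DilationSpec((0, 0, 0)))
        assert rep.iloc[0]["gtvp"] == rep[rep.case_id == "mean"].iloc[0]["gtvp"]


@settings(deadline=None, max_examples=20)
@given(st.integers(0, 3), st.integers(0, 3))
def test_overlap_monotone_in_dilation_radius(r1, r2):
    """Coverage of the mid mask never decreases as the margin grows."""
    rng = np.random.default_rng(5)
    pre = np.zeros((14, 14, 8), dtype=np.int16)
    pre[5:8, 5:8, 3:5] = 1
    mid = np.zeros_like(pre)
    mid[4:9, 4:9, 2:6] = 1
    mv, pv = LabelVolume(mid, (1, 1, 2)), LabelVolume(pre, (1, 1, 2))
    lo, hi = sorted((r1, r2))
    a = overlap_ratio(mv, dilate_mask(pv, DilationSpec((lo, lo, lo))), 1)
    b = overlap_ratio(mv, dilate_mask(pv, DilationSpec((hi, hi, hi))), 1)
    assert b >= a
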