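import numpy as np
import pytest

from striascope import (RoiMask, SegmentationError, SummedImage,
                        compute_intensity_features, compute_shape_features,
                        find_striatal_max_slice, make_summed_image,
                        mask_perimeter, segment_striatum)
from _oracles import disk_mask, rect_mask


def roi(mask, pixel_mm=1.0, side="left"):
    return RoiMask(mask=mask, side=side, pixel_mm=(pixel_mm, pixel_mm))


def image(data, voxel=(1.0, 1.0)):
    return SummedImage(data=np.asarray(data, dtype=float), center_slice=0,
                       slice_range=(0, 0), voxel_mm=voxel)


class TestShapeFeaturesGeometry:
    def test_disk_is_nearly_circular(self):
        """Rasterized disk of radius 30 px at 1 mm/px."""
        sf = compute_shape_features(roi(disk_mask(30)))
        assert sf.circularity == pytest.approx(1.0, abs=0.05)
        assert sf.area == pytest.approx(np.pi * 30**2, rel=0.02)
        assert sf.major_axis_length / sf.minor_axis_length == \
            pytest.approx(1.0, rel=0.02)

    def test_rectangle_matches_analytic_shape(self):
        """60x20 px rectangle: axis ratio 3, circularity near 4*pi*S/L^2 = 0.589."""
        sf = compute_shape_features(roi(rect_mask(60, 20)))
        assert sf.major_axis_length / sf.minor_axis_length == \
            pytest.approx(3.0, rel=0.02)
        assert sf.circularity == pytest.approx(0.589, rel=0.035)

    def test_circularity_internal_consistency(self):
        """circularity and equivalent diameter recompute from area/perimeter."""
        sf = compute_shape_features(roi(disk_mask(17)))
        assert sf.circularity == pytest.approx(
            4 * np.pi * sf.area / sf.perimeter**2, abs=1e-12)
        assert sf.equivalent_diameter == pytest.approx(
            np.sqrt(4 * sf.area / np.pi), abs=1e-12)

    def test_area_exact_from_pixel_count(self):
        """Area and equivalent diameter are exact functions of pixel count."""
        rng = np.random.default_rng(0)
        blob = disk_mask(9)
        sf = compute_shape_features(roi(blob, pixel_mm=2.0))
        assert sf.area == pytest.approx(blob.sum() * 4.0, abs=1e-12)

    @pytest.mark.parametrize("mask", [disk_mask(12), rect_mask(40, 15)],
                             ids=["disk", "rect"])
    def test_rotation_by_90_degrees_invariant(self, mask):
        a = compute_shape_features(roi(mask))
        b = compute_shape_features(roi(np.rot90(mask).copy()))
        assert b.area == a.area
        assert b.perimeter == pytest.approx(a.perimeter, rel=0.01)
        assert b.major_axis_length == pytest.approx(a.major_axis_length, rel=0.01)
        assert b.minor_axis_length == pytest.approx(a.minor_axis_length, rel=0.01)

    def test_pixel_size_rescaling(self):
        """2 mm/px vs 1 mm/px: area x4, lengths x2, circularity unchanged."""
        m = disk_mask(14)
        f1 = compute_shape_features(roi(m, pixel_mm=1.0))
        f2 = compute_shape_features(roi(m, pixel_mm=2.0))
        assert f2.area == pytest.approx(4 * f1.area, abs=1e-9)
        assert f2.perimeter == pytest.approx(2 * f1.perimeter, abs=1e-9)
        assert f2.major_axis_length == pytest.approx(2 * f1.major_axis_length)
        assert f2.equivalent_diameter == pytest.approx(2 * f1.equivalent_diameter)
        assert f2.circularity == pytest.approx(f1.circularity, abs=1e-12)

    def test_disk_circularity_converges_monotonically_to_one(self):
        errs = [abs(1.0 - compute_shape_features(roi(disk_mask(r))).circularity)
                for r in (10, 20, 40, 80)]
        assert all(b < a for a, b in zip(errs, errs[1:])), errs

    @pytest.mark.parametrize("mask", [
        disk_mask(6), disk_mask(25), rect_mask(10, 10), rect_mask(50, 35),
    ], ids=["disk6", "disk25", "square10", "rect50x35"])
    def test_convex_shapes_respect_isoperimetric_bound(self, mask):
        """Circularity stays <= 1 + eps under the frozen perimeter convention."""
        assert compute_shape_features(roi(mask)).circularity <= 1.0 + 0.01

    def test_elongation_lowers_circularity_and_grows_major_axis(self):
        """Rectangles of equal area, increasingly elongated."""
        shapes = [(40, 30), (60, 20), (80, 15), (120, 10)]  # area 1200 each
        feats = [compute_shape_features(roi(rect_mask(h, w))) for h, w in shapes]
        circs = [f.circularity for f in feats]
        majors = [f.major_axis_length for f in feats]
        assert all(a > b for a, b in zip(circs, circs[1:])), circs
        assert all(a < b for a, b in zip(majors, majors[1:])), majors

    def test_hole_filled_before_perimeter(self):
        full = disk_mask(10)
        c = full.shape[0] // 2
        yy, xx = np.mgrid[: full.shape[0], : full.shape[1]]
        annulus = full & ((yy - c) ** 2 + (xx - c) ** 2 > 4**2)
        # annulus is one 8-connected component with an interior hole
        sf = compute_shape_features(roi(annulus))
        full = compute_shape_features(roi(disk_mask(10)))
        assert sf.area == full.area
        assert sf.perimeter == pytest.approx(full.perimeter, abs=1e-9)


class TestRoiMaskValidation:
    def test_rejects_empty_mask(self):
        with pytest.raises(ValueError, match="empty"):
            roi(np.zeros((10, 10), dtype=bool))

    def test_rejects_disconnected_mask(self):
        m = np.zeros((20, 20), dtype=bool)
        m[2:5, 2:5] = True
        m[10:13, 10:13] = True
        with pytest.raises(ValueError, match="connected"):
            roi(m)

    def test_rejects_unknown_side(self):
        with pytest.raises(ValueError, match="side"):
            RoiMask(mask=disk_mask(3), side="up", pixel_mm=(1.0, 1.0))


class TestSegmentStriatum:
    def test_two_disks_on_zero_background_recovered_exactly(self):
        data = np.zeros((60, 40))
        left_disk = np.zeros_like(data, dtype=bool)
        right_disk = np.zeros_like(data, dtype=bool)
        yy, xx = np.mgrid[:60, :40]
        left_disk[(yy - 15)**2 + (xx - 20)**2 <= 49] = True
        right_disk[(yy - 45)**2 + (xx - 20)**2 <= 49] = True
        data[left_disk] = 10.0
        data[right_disk] = 10.0
        left, right = segment_striatum(image(data), threshold_fraction=0.5)
        np.testing.assert_array_equal(left.mask, left_disk)
        np.testing.assert_array_equal(right.mask, right_disk)

    def test_largest_component_kept(self):
        data = np.zeros((60, 40))
        data[5:8, 5:8] = 10.0     # small distractor, left hemifield
        data[15:25, 10:25] = 10.0  # main blob, left hemifield
        data[40:50, 10:25] = 10.0  # right hemifield blob
        left, _ = segment_striatum(image(data), threshold_fraction=0.5)
        assert left.n_pixels == 10 * 15

    def test_zero_hemifield_raises_segmentation_error(self):
        data = np.zeros((60, 40))
        data[40:50, 10:20] = 5.0  # right hemifield only
        with pytest.raises(SegmentationError, match="left"):
            segment_striatum(image(data))

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold_fraction"):
            segment_striatum(image(np.ones((10, 10))), threshold_fraction=1.5)

    def test_masks_overlap_projected_truth_on_clean_phantom(self, nc_phantom_clean):
        """Dice vs the summed truth striatum exceeds 0.7 per side (noise off)."""
        ph = nc_phantom_clean
        z = find_striatal_max_slice(ph.volume, ph.parotid_boundary())
        summed = make_summed_image(ph.volume, z)
        lo, hi = summed.slice_range
        left, right = segment_striatum(summed)
        mid = summed.data.shape[0] // 2
        truth3d = (ph.truth_masks["caudate_left"] | ph.truth_masks["caudate_right"]
                   | ph.truth_masks["putamen_left"] | ph.truth_masks["putamen_right"])
        truth = truth3d[:, :, lo:hi + 1].any(axis=2)
        for m in (left, right):
            side_truth = truth.copy()
            if m.side == "left":
                side_truth[mid:] = False
            else:
                side_truth[:mid] = False
            inter = (m.mask & side_truth).sum()
            dice = 2 * inter / (m.mask.sum() + side_truth.sum())
            assert dice > 0.7, (m.side, dice)


class TestIntensityFeatures:
    def test_constant_image(self):
        m = disk_mask(4)
        feats = compute_intensity_features(roi(m), image(np.full(m.shape, 5.0)))
        assert (feats.max_count, feats.min_count, feats.mean_count) == (5, 5, 5)

    def test_two_pixel_mask(self):
        data = np.zeros((5, 5))
        data[2, 2], data[2, 3] = 1.0, 3.0
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = m[2, 3] = True
        feats = compute_intensity_features(roi(m), image(data))
        assert (feats.max_count, feats.min_count, feats.mean_count) == (3, 1, 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            compute_intensity_features(roi(disk_mask(3)), image(np.ones((4, 4))))

    def test_roi_hotter_than_reference_on_phantom(self, nc_phantom_clean):
        ph = nc_phantom_clean
        z = find_striatal_max_slice(ph.volume, ph.parotid_boundary())
        summed = make_summed_image(ph.volume, z)
        lo, hi = summed.slice_range
        left, _ = segment_striatum(summed)
        feats = compute_intensity_features(left, summed)
        occ = ph.truth_masks["occipital"][:, :, lo:hi + 1].any(axis=2)
        assert feats.max_count >= summed.data[occ].mean()
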