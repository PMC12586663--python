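import math

import numpy as np
import pytest

from ccmorph.core import BinaryMask2D
from ccmorph.morphometry import (
    EmptyMaskError,
    cc_length,
    centerline_curvature,
    mean_thickness,
    perimeter,
    shape_record,
    thickness_profile,
    total_area,
    witelson_parcellate,
)
from conftest import make_band_mask


def brute_force_metrics(mask: BinaryMask2D):
    """Independent per-pixel oracle: area, per-column extents, AP extent."""
    px = mask.pixels
    area = 0
    col_extents = {}
    for r in range(px.shape[0]):
        for c in range(px.shape[1]):
            if px[r, c]:
                area += 1
                lo, hi = col_extents.get(c, (r, r))
                col_extents[c] = (min(lo, r), max(hi, r))
    thicknesses = {c: hi - lo + 1 for c, (lo, hi) in col_extents.items()}
    cols = sorted(col_extents)
    length = cols[-1] - cols[0] + 1 if cols else 0
    return area, thicknesses, length


class TestTotalArea:
    def test_empty_mask_is_zero(self):
        assert total_area(BinaryMask2D(np.zeros((64, 64)))) == 0.0

    def test_band_area(self):
        assert total_area(make_band_mask(height=6, width=20)) == 120.0

    def test_pixel_size_scales_area(self):
        mask = make_band_mask(height=6, width=20, pixel_size_mm=2.0)
        assert total_area(mask) == 120.0 * 4.0

    def test_phantom_matches_brute_force(self, phantom_masks):
        for mask in phantom_masks[:5]:
            area, _, _ = brute_force_metrics(mask)
            assert total_area(mask) == float(area)


class TestThicknessProfile:
    def test_band_profile_constant(self):
        prof = thickness_profile(make_band_mask(height=6, width=30))
        assert len(prof.columns) == 30
        assert np.all(prof.thickness_mm == 6.0)

    def test_single_pixel(self):
        px = np.zeros((64, 64))
        px[10, 20] = 1
        prof = thickness_profile(BinaryMask2D(px))
        assert list(prof.thickness_mm) == [1.0]

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            thickness_profile(BinaryMask2D(np.zeros((64, 64))))

    def test_phantom_matches_column_oracle(self, phantom_masks):
        for mask in phantom_masks[:5]:
            _, oracle, _ = brute_force_metrics(mask)
            prof = thickness_profile(mask)
            assert {int(c): t for c, t in zip(prof.columns, prof.thickness_mm)} == {
                c: float(t) for c, t in oracle.items()
            }

    def test_holes_do_not_shrink_extent_thickness(self):
        solid = make_band_mask(height=8, width=20)
        holed = solid.copy()
        holed.pixels[23:25, 15:20] = 0  # interior hole
        assert np.all(
            thickness_profile(holed).thickness_mm
            == thickness_profile(solid).thickness_mm
        )


class TestMeanThickness:
    def test_band_total(self):
        assert mean_thickness(make_band_mask(height=6)) == 6.0

    def test_staircase_hand_mean(self):
        px = np.zeros((64, 64))
        px[20:24, 10:20] = 1  # 10 columns of height 4
        px[20:28, 20:30] = 1  # 10 columns of height 8
        assert mean_thickness(BinaryMask2D(px)) == 6.0

    def test_region_means_match_oracle(self, phantom_masks):
        for mask in phantom_masks[:5]:
            labels = witelson_parcellate(mask)
            for code in range(1, 6):
                sub = BinaryMask2D(labels.region_mask(code).astype(np.uint8))
                _, oracle, _ = brute_force_metrics(sub)
                expected = np.mean(list(oracle.values()))
                assert mean_thickness(mask, labels, code) == pytest.approx(expected)

    def test_empty_region_is_missing_not_zero(self):
        mask = make_band_mask()
        labels = witelson_parcellate(mask)
        labels.labels[labels.labels == 5] = 0  # artificially empty a region
        assert math.isnan(mean_thickness(mask, labels, 5))


class TestWitelsonParcellate:
    def test_band_region_areas_by_fraction_arithmetic(self):
        # 30 columns cut at 10/5/5/4/6, height 6
        labels = witelson_parcellate(make_band_mask(height=6, width=30))
        areas = [int(labels.region_mask(c).sum()) for c in range(1, 6)]
        assert areas == [60, 30, 30, 24, 36]
        assert sum(areas) == 180

    def test_translation_invariance(self):
        a = witelson_parcellate(make_band_mask(col0=0, n_cols=130, width=30))
        b = witelson_parcellate(make_band_mask(col0=100, n_cols=130, width=30))
        areas_a = [int(a.region_mask(c).sum()) for c in range(1, 6)]
        areas_b = [int(b.region_mask(c).sum()) for c in range(1, 6)]
        assert areas_a == areas_b

    def test_partition_is_exact_on_phantoms(self, phantom_masks):
        for mask in phantom_masks:
            labels = witelson_parcellate(mask)
            region_sum = sum(labels.region_mask(c).sum() for c in range(1, 6))
            assert region_sum == mask.area_pixels
            # labels live exactly on the mask
            assert np.array_equal(labels.labels > 0, mask.pixels > 0)

    def test_narrow_mask_rejected(self):
        with pytest.raises(ValueError, match="5"):
            witelson_parcellate(make_band_mask(width=4))

    def test_codes_increase_anterior_to_posterior(self, phantom_masks):
        labels = witelson_parcellate(phantom_masks[0]).labels
        cols_by_code = [
            np.flatnonzero((labels == c).any(axis=0)) for c in range(1, 6)
        ]
        for earlier, later in zip(cols_by_code, cols_by_code[1:]):
            assert earlier.max() < later.min()


class TestCcLength:
    def test_band_length(self):
        assert cc_length(make_band_mask(width=30)) == 30.0

    def test_single_pixel(self):
        px = np.zeros((64, 64))
        px[5, 5] = 1
        assert cc_length(BinaryMask2D(px)) == 1.0

    def test_phantom_matches_oracle(self, phantom_masks):
        for mask in phantom_masks[:5]:
            _, _, length = brute_force_metrics(mask)
            assert cc_length(mask) == float(length)


class TestPerimeter:
    def test_square_close_to_analytic(self):
        px = np.zeros((30, 30))
        px[10:20, 10:20] = 1
        assert perimeter(BinaryMask2D(px)) == pytest.approx(36.0, rel=0.10)

    def test_pixel_doubling_doubles_perimeter(self, phantom_masks):
        mask = phantom_masks[0]
        big = BinaryMask2D(np.kron(mask.pixels, np.ones((2, 2), dtype=np.uint8)))
        ratio = perimeter(big) / perimeter(mask)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_hole_strictly_increases_perimeter(self):
        solid = make_band_mask(height=10, width=20)
        holed = solid.copy()
        holed.pixels[24:26, 18:22] = 0
        assert perimeter(holed) > perimeter(solid)

    def test_border_touching_component_still_closes(self):
        px = np.zeros((20, 20))
        px[0:10, 0:10] = 1  # corner block: contour must close via padding
        assert perimeter(BinaryMask2D(px)) == pytest.approx(4 * 10, rel=0.15)


class TestCenterlineCurvature:
    def test_straight_band_is_flat(self):
        assert centerline_curvature(make_band_mask()) < 1e-6

    def test_circular_arc_recovers_radius(self):
        # annulus arc of radius 50 centered below the image:
        # column midpoints lie on the radius-50 circle
        radius, halfwidth = 50.0, 3.0
        rows, cols = 80, 120
        cy, cx = -10.0, 60.0  # center below the grid
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        d = np.hypot(rr - cy, cc - cx)
        theta = np.degrees(np.arctan2(rr - cy, cc - cx))
        px = ((np.abs(d - radius) <= halfwidth) & (theta > 60) & (theta < 120)).astype(
            np.uint8
        )
        kappa = centerline_curvature(BinaryMask2D(px))
        assert kappa == pytest.approx(1.0 / radius, rel=0.15)

    def test_translation_invariance(self, phantom_masks):
        mask = phantom_masks[0]
        shifted = BinaryMask2D(np.roll(mask.pixels, 3, axis=1))
        assert centerline_curvature(shifted) == pytest.approx(
            centerline_curvature(mask), abs=1e-12
        )

    def test_too_narrow_mask_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            centerline_curvature(make_band_mask(width=3))


class TestShapeRecord:
    def test_band_record_composes_operations(self):
        mask = make_band_mask(height=6, width=30)
        rec = shape_record(mask, "band")
        assert rec.total_area == 180.0
        assert rec.region_areas == (60.0, 30.0, 30.0, 24.0, 36.0)
        assert rec.total_mean_thickness == 6.0
        assert rec.length == 30.0
        assert rec.valid

    def test_empty_mask_is_invalid_record(self):
        rec = shape_record(BinaryMask2D(np.zeros((64, 64))), "empty")
        assert not rec.valid
        assert rec.total_area == 0.0
        assert math.isnan(rec.length)

    def test_batch_partition_invariants(self, phantom_masks):
        for i, mask in enumerate(phantom_masks):
            rec = shape_record(mask, f"p{i}")
            assert sum(rec.region_areas) == pytest.approx(rec.total_area)
            thicknesses = rec.region_mean_thickness
            assert min(thicknesses) <= rec.total_mean_thickness <= max(thicknesses)
            prof_max = rec.total_mean_thickness  # mean <= max extent
            assert rec.total_area <= rec.length * max(thicknesses)


class TestSymmetry:
    def test_180_rotation_swaps_genu_and_splenium(self, phantom_masks):
        # The Witelson cuts are not symmetric about the midpoint, so the
        # rotated mask is parcellated with the reversed complement
        # fractions.  The half-open cut convention shifts each cut by
        # exactly one column under mirroring, so the flipped-back label
        # map may differ from 6-minus-original only on cut columns.
        mask = phantom_masks[0]
        rotated = BinaryMask2D(mask.pixels[::-1, ::-1].copy())
        mirrored = tuple(sorted(1.0 - f for f in (1 / 3, 1 / 2, 2 / 3, 4 / 5)))
        labels = witelson_parcellate(mask).labels
        labels_back = witelson_parcellate(rotated, mirrored).labels[::-1, ::-1]
        swapped = np.where(labels > 0, 6 - labels, 0)
        diff_cols = np.flatnonzero((labels_back != swapped).any(axis=0))
        assert diff_cols.size <= 4  # at most the 4 cut-boundary columns
        # and where they differ, codes are off by exactly one region
        assert np.all(np.abs(labels_back[:, diff_cols] - swapped[:, diff_cols])
                      * (labels[:, diff_cols] > 0) <= 1)
        rec = shape_record(mask)
        rec_rot = shape_record(rotated, fractions=mirrored)
        assert rec_rot.total_area == rec.total_area
        assert rec_rot.length == rec.length
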