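"""Arclength geometry, kymograph sampling, and the position→volume map."""

import numpy as np
import pytest

from sngfr.io import AcquisitionMeta, FrameSeries, PolylineROI
from sngfr.mapping import (
    arclength_grid,
    build_kymograph,
    map_cumulative_volume,
    project_points_to_polyline,
    sample_profile,
)
from sngfr.segment import TubuleMask


class TestArclengthGrid:
    def test_axis_aligned_segment(self):
        g = arclength_grid(PolylineROI([[0, 0], [10, 0]]), pixel_size_um=1.0, spacing_um=1.0)
        np.testing.assert_allclose(g.positions_um, np.arange(11))
        assert g.length_um == pytest.approx(10.0)
        np.testing.assert_allclose(g.points_px[:, 0], np.arange(11.0))

    def test_right_angle_three_four_five(self):
        g = arclength_grid(PolylineROI([[0, 0], [3, 0], [3, 4]]), 1.0, 1.0)
        assert g.length_um == pytest.approx(7.0)

    def test_random_polyline_length_equals_segment_sum(self, rng):
        verts = rng.uniform(0, 50, size=(9, 2))
        px = 0.8513
        g = arclength_grid(PolylineROI(verts), px)
        oracle = sum(
            np.hypot(x1 - x0, y1 - y0) * px
            for (x0, y0), (x1, y1) in zip(verts[:-1], verts[1:])
        )
        assert g.length_um == pytest.approx(oracle, rel=1e-12)

    def test_sample_points_lie_on_polyline(self, rng):
        verts = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0]])
        g = arclength_grid(PolylineROI(verts), 1.0, 0.5)
        s, d = project_points_to_polyline(g.points_px, PolylineROI(verts), 1.0)
        np.testing.assert_allclose(d, 0.0, atol=1e-9)
        np.testing.assert_allclose(s, g.positions_um, atol=1e-9)


class TestSampleProfile:
    def test_constant_frame_any_width(self):
        frame = np.full((20, 20), 7.0)
        pts = np.column_stack([np.linspace(2, 17, 10), np.full(10, 9.3)])
        tangents = np.tile([1.0, 0.0], (10, 1))
        for w in (1, 3, 5):
            np.testing.assert_allclose(sample_profile(frame, pts, w, tangents), 7.0)

    def test_linear_gradient_is_sampled_exactly(self):
        frame = np.tile(np.arange(30.0), (10, 1))  # I = x
        xs = np.linspace(1.2, 27.9, 15)
        pts = np.column_stack([xs, np.full(15, 4.0)])
        np.testing.assert_allclose(sample_profile(frame, pts), xs)

    def test_width3_equals_mean_of_parallel_profiles(self, rng):
        frame = rng.uniform(0, 100, size=(40, 40))
        xs = np.linspace(5, 34, 12)
        pts = np.column_stack([xs, np.full(12, 20.0)])
        tangents = np.tile([1.0, 0.0], (12, 1))
        wide = sample_profile(frame, pts, 3, tangents)
        oracle = np.mean(
            [
                sample_profile(frame, pts + np.array([0.0, dy]))
                for dy in (-1.0, 0.0, 1.0)
            ],
            axis=0,
        )
        np.testing.assert_allclose(wide, oracle, rtol=1e-12)

    def test_point_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            sample_profile(np.zeros((5, 5)), np.array([[4.5, 2.0]]))


class TestKymograph:
    def test_constant_series_gives_identical_columns(self):
        meta = AcquisitionMeta(pixel_size_um=1.0)
        frames = np.full((3, 16, 16), 5.0)
        series = FrameSeries(frames, meta)
        kymo, _ = build_kymograph(series, PolylineROI([[1, 8], [14, 8]]))
        assert kymo.values.shape[1] == 3
        np.testing.assert_allclose(kymo.values, 5.0)

    def test_phantom_front_advances_monotonically(self, clean_phantom):
        spec, series, volumes, roi, truth = clean_phantom
        kymo, _ = build_kymograph(series, roi)
        half = 0.5 * spec.intensity_max
        crossings = []
        for t in range(kymo.n_frames):
            above = kymo.values[:, t] >= half
            crossings.append(above.sum())  # run length of the bright region
        assert all(b >= a for a, b in zip(crossings, crossings[1:]))

    def test_frame_zero_blank_before_injection(self, clean_phantom):
        _, series, _, roi, _ = clean_phantom
        kymo, _ = build_kymograph(series, roi)
        assert kymo.values[:, 0].max() <= 1e-9

    def test_offset_linearity(self, clean_phantom):
        """Adding a constant to every frame shifts the kymograph by that constant."""
        spec, series, _, roi, _ = clean_phantom
        kymo, _ = build_kymograph(series, roi)
        shifted = FrameSeries(series.frames + 11.0, series.meta)
        kymo2, _ = build_kymograph(shifted, roi)
        np.testing.assert_allclose(kymo2.values, kymo.values + 11.0, rtol=1e-6)


class TestCumulativeVolume:
    def _cylinder_mask(self, r_um, nx=60, ny=40, nz=20, px=1.0, dz=1.0):
        """Straight cylinder along x, centered in y and z."""
        zz, yy, xx = np.indices((nz, ny, nx)).astype(float)
        d = np.sqrt(((yy - ny / 2) * px) ** 2 + ((zz - nz / 2) * dz) ** 2)
        mask = d <= r_um
        return TubuleMask(mask, (dz, px, px))

    def test_cylinder_matches_closed_form(self):
        r, px = 5.0, 1.0
        mask = self._cylinder_mask(r)
        roi = PolylineROI([[0, 20], [59, 20]])
        positions = np.arange(60.0)
        vp = map_cumulative_volume(mask, roi, positions, px)
        area = np.pi * r**2
        # interior slope equals πr² within voxelization error (≤5% at r ≥ 4 voxels)
        slope = (vp.cumvol_um3[50] - vp.cumvol_um3[10]) / 40.0
        assert slope == pytest.approx(area, rel=0.05)
        # pointwise: πr²·s plus at most one cross-sectional slab of discretization
        err = np.abs(vp.cumvol_um3 - area * positions)
        assert np.all(err <= 0.05 * area * positions + 1.1 * area * px)
        assert vp.total_um3 == pytest.approx(mask.volume_um3, rel=1e-12)

    def test_leading_zeros_before_tubule_starts(self):
        mask = self._cylinder_mask(3.0)
        trimmed = mask.mask.copy()
        trimmed[:, :, :20] = False  # tubule starts 20 µm in
        mask2 = TubuleMask(trimmed, mask.voxel_dims)
        roi = PolylineROI([[0, 20], [59, 20]])
        vp = map_cumulative_volume(mask2, roi, np.arange(60.0), 1.0)
        assert np.all(vp.cumvol_um3[:19] == 0)
        assert vp.cumvol_um3[-1] > 0

    def test_all_voxels_beyond_roi_end_rejected(self):
        mask = self._cylinder_mask(3.0)
        trimmed = mask.mask.copy()
        trimmed[:, :, :50] = False
        mask2 = TubuleMask(trimmed, mask.voxel_dims)
        roi = PolylineROI([[0, 20], [10, 20]])  # ends before the remaining voxels
        with pytest.raises(ValueError, match="projects inside"):
            map_cumulative_volume(mask2, roi, np.arange(11.0), 1.0)

    def test_profile_non_decreasing_and_ends_at_total(self, clean_phantom):
        spec, _, _, roi, truth = clean_phantom
        vox = (spec.meta.voxel_depth_um, spec.meta.pixel_size_um, spec.meta.pixel_size_um)
        mask = TubuleMask(truth.tube_mask, vox)
        g = arclength_grid(roi, spec.meta.pixel_size_um)
        vp = map_cumulative_volume(mask, roi, g.positions_um, spec.meta.pixel_size_um)
        assert np.all(np.diff(vp.cumvol_um3) >= 0)
        assert vp.total_um3 <= mask.volume_um3 + 1e-9

    def test_reversal_complements_assignments(self):
        """Reversing the ROI maps each voxel's arclength s to L − s."""
        from sngfr import default_spec, render_phantom

        spec = default_spec(centerline="sine", bend_amplitude_px=6.0)
        _, _, roi, truth = render_phantom(spec)
        px = spec.meta.pixel_size_um
        zyx = np.argwhere(truth.tube_mask)
        pts = zyx[:, [2, 1]].astype(float)
        s_fwd, d_fwd = project_points_to_polyline(pts, roi, px)
        s_rev, d_rev = project_points_to_polyline(pts, roi.reversed(), px)
        g = arclength_grid(roi, px)
        np.testing.assert_allclose(s_fwd + s_rev, g.length_um, atol=1e-6)
        np.testing.assert_allclose(d_fwd, d_rev, atol=1e-6)

    def test_projection_ties_resolve_to_smaller_arclength(self):
        # right-angle polyline: the inner corner point is equidistant to both segments
        roi = PolylineROI([[0, 0], [10, 0], [10, 10]])
        s, d = project_points_to_polyline(np.array([[9.0, 1.0]]), roi, 1.0)
        assert d[0] == pytest.approx(1.0)
        assert s[0] == pytest.approx(9.0)  # not 11.0 via the second segment
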