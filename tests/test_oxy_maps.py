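"""Oxygen-demand map construction: gradients, zero zones, closed forms."""

import numpy as np
import pytest
from scipy import ndimage

from lungphantom import (
    AnthroMapParams,
    InvalidConfigurationError,
    PreconditionError,
    SegmentMapParams,
    VoxelGrid,
    build_anthro_airway_map,
    build_anthro_artery_map,
    build_anthro_vein_map,
    build_segment_airway_map,
    build_segment_artery_map,
    build_segment_vein_map,
)
from lungphantom.oxy_maps import _core_box


def chessboard_from_core(shape, core_fraction):
    core = _core_box(shape, core_fraction)
    return ndimage.distance_transform_cdt(~core, metric="chessboard")


class TestSegmentArteryMap:
    def test_center_is_one_and_corners_share_minimum(self):
        m = build_segment_artery_map((21, 21, 21)).values
        assert m[10, 10, 10] == 1.0
        corners = [m[i, j, k] for i in (0, -1) for j in (0, -1) for k in (0, -1)]
        assert np.allclose(corners, m.min())

    def test_monotone_nonincreasing_in_chessboard_distance(self):
        """Brute-force scan: demand never increases as the chessboard
        distance from the core grows."""
        params = SegmentMapParams()
        m = build_segment_artery_map((21, 21, 21), params).values
        d = chessboard_from_core((21, 21, 21), params.core_fraction)
        for dist in range(d.max()):
            assert m[d == dist].min() >= m[d == dist + 1].max() - 1e-12

    def test_values_in_unit_interval_with_max_one(self):
        m = build_segment_artery_map((15, 17, 19)).values
        assert m.min() >= 0.0 and m.max() == 1.0

    def test_degenerate_shape_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            build_segment_artery_map((2, 21, 21))


class TestSegmentAirwayMap:
    def test_single_artery_voxel_profile(self):
        """Euclidean-distance oracle on the single-voxel case: zero at the
        artery and its margin, positive in the proximity shell, zero far."""
        art = np.zeros((31, 31, 31), dtype=np.uint8)
        art[15, 15, 15] = 1
        params = SegmentMapParams(r_max=3.0, margin=1)
        m = build_segment_airway_map(VoxelGrid(art), params).values
        d = ndimage.distance_transform_edt(art == 0)
        assert m[15, 15, 15] == 0.0
        assert m[15, 15, 16] == 0.0  # margin voxel
        shell = (d > 2) & (d <= 2 * params.r_max)
        assert m[shell].max() > 0
        assert np.all(m[d > 2 * params.r_max + params.r_max_decay] == 0.0)

    def test_dilated_artery_voxels_have_zero_demand(self):
        rng = np.random.default_rng(0)
        art = (rng.random((25, 25, 25)) < 0.01).astype(np.uint8)
        art[12, 12, 12] = 1
        params = SegmentMapParams(margin=2)
        m = build_segment_airway_map(VoxelGrid(art), params).values
        dil = ndimage.binary_dilation(
            art > 0, structure=ndimage.generate_binary_structure(3, 1), iterations=2
        )
        assert np.all(m[dil] == 0.0)

    def test_max_is_one_and_empty_arteries_rejected(self):
        art = np.zeros((15, 15, 15), dtype=np.uint8)
        with pytest.raises(PreconditionError):
            build_segment_airway_map(VoxelGrid(art))
        art[7, 7, 7] = 1
        assert build_segment_airway_map(VoxelGrid(art)).values.max() == 1.0


class TestSegmentVeinMap:
    def test_inverse_gradient(self):
        m = build_segment_vein_map((21, 21, 21)).values
        corners = [m[i, j, k] for i in (0, -1) for j in (0, -1) for k in (0, -1)]
        assert np.allclose(corners, 1.0)
        assert m[10, 10, 10] == m.min()

    def test_occupied_voxels_zeroed_with_margin(self):
        occ = np.zeros((21, 21, 21), dtype=np.uint8)
        occ[3, 3, 3] = 1
        m = build_segment_vein_map((21, 21, 21), VoxelGrid(occ), SegmentMapParams(margin=1)).values
        assert m[3, 3, 3] == 0.0 and m[3, 3, 4] == 0.0

    def test_artery_and_vein_peaks_disjoint(self):
        """Brute-force argmax comparison: the two maps peak in different
        voxel sets."""
        art = build_segment_artery_map((21, 21, 21)).values
        vein = build_segment_vein_map((21, 21, 21)).values
        art_peaks = set(map(tuple, np.argwhere(art == art.max())))
        vein_peaks = set(map(tuple, np.argwhere(vein == vein.max())))
        assert not art_peaks & vein_peaks


class TestAnthroArteryMap:
    def _setup(self):
        lung = np.ones((31, 31, 31), dtype=np.uint8)
        cl = np.zeros_like(lung)
        cl[15, 15, 15] = 1
        return VoxelGrid(cl), VoxelGrid(lung)

    def test_linear_ramp_closed_form(self):
        """Inside the lung the map equals max(0, 1 - d_E/dmax) with d_E the
        per-voxel distance to the centerline (direct oracle)."""
        cl, lung = self._setup()
        m = build_anthro_artery_map(cl, lung, AnthroMapParams(oxy_dmax=10.0)).values
        idx = np.indices(m.shape)
        d = np.sqrt(((idx - 15) ** 2).sum(axis=0))
        assert np.allclose(m, np.clip(1.0 - d / 10.0, 0, 1), atol=1e-12)

    def test_centerline_one_and_far_zero_and_midpoint_half(self):
        cl, lung = self._setup()
        m = build_anthro_artery_map(cl, lung, AnthroMapParams(oxy_dmax=10.0)).values
        assert m[15, 15, 15] == 1.0
        assert m[15, 15, 25] == 0.0  # exactly 10 mm
        assert m[15, 15, 20] == pytest.approx(0.5)  # 5 mm

    def test_outside_lung_zero_and_empty_centerline_rejected(self):
        cl, lung = self._setup()
        lung.values[:5] = 0
        m = build_anthro_artery_map(cl, lung).values
        assert np.all(m[:5] == 0.0)
        with pytest.raises(PreconditionError):
            build_anthro_artery_map(lung.like(np.zeros_like(cl.values)), lung)


class TestAnthroAirwayMap:
    def test_zero_outside_hull_and_beyond_cutoff(self):
        lung = VoxelGrid(np.ones((41, 41, 41), dtype=np.uint8))
        art = np.zeros_like(lung.values)
        art[20, 18, 20] = 1
        air = np.zeros_like(lung.values)
        air[18:23, 20:25, 18:23] = 1  # solid box: hull equals the box
        params = SegmentMapParams(r_max=1.5, margin=0)
        m = build_anthro_airway_map(VoxelGrid(art), VoxelGrid(air), lung, params).values
        hull = air > 0
        assert np.all(m[~hull] == 0.0)
        d = ndimage.distance_transform_edt(art == 0)
        cutoff = 2 * params.r_max + params.r_max_decay
        assert np.all(m[hull & (d > cutoff)] == 0.0)
        assert m.max() == 1.0


class TestAnthroVeinMap:
    def _setup(self):
        lung = np.zeros((41, 41, 41), dtype=np.uint8)
        lung[5:36, 5:36, 5:36] = 1
        occ = np.zeros_like(lung)
        occ[8:33, 19:22, 19:22] = 1  # central rod of arteries+airways
        return VoxelGrid(occ), VoxelGrid(lung)

    def test_zero_outside_lung_and_on_structures(self):
        occ, lung = self._setup()
        m = build_anthro_vein_map(occ, lung).values
        assert np.all(m[lung.values == 0] == 0.0)
        assert np.all(m[occ.values > 0] == 0.0)

    def test_floor_value_far_from_venous_centerline(self):
        occ, lung = self._setup()
        params = AnthroMapParams(oxy_dmax=5.0, ox_min=0.001)
        m = build_anthro_vein_map(occ, lung, params).values
        in_lung = (lung.values > 0) & (occ.values == 0)
        positives = m[in_lung]
        assert positives.min() == pytest.approx(0.001)
        assert m.max() == 1.0

    def test_fully_occupied_lung_rejected(self):
        occ, lung = self._setup()
        with pytest.raises(PreconditionError):
            build_anthro_vein_map(lung.like(lung.values.copy()), lung)
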