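"""Airway hollowing, HU mapping, deformation, and CT composition."""

import numpy as np
import pytest

from lungphantom import (
    DeformationParams,
    IntensityModel,
    NoiseParams,
    Tree,
    VoxelGrid,
    WallThicknessTable,
    compose_phantom,
    deform_structures,
    embed_phantom,
    hollow_airways,
    jacobian_determinants,
    map_intensities,
    rasterize_tree,
)


def _tube(a, b, radius, shape=(41, 21, 21)):
    tree = Tree.with_root(a)
    child = tree.add_child(tree.root_id, b)
    tree.radius[child] = radius
    grid = VoxelGrid(np.zeros(shape))
    gray, _ = rasterize_tree(tree, grid, supersampling=3)
    return tree, gray


class TestHollowAirways:
    def test_half_ratio_leaves_tube_opaque(self):
        tree, gray = _tube((5, 10, 10), (35, 10, 10), 2.0)
        out = hollow_airways(gray, tree, WallThicknessTable(ratios=(0.5,)))
        assert np.array_equal(out.values, gray.values)

    def test_wall_thickness_matches_ratio(self):
        """r = 2 mm, WT/D = 0.2 gives a 0.8 mm wall; measured across a
        perpendicular intensity profile within half a voxel."""
        tree, gray = _tube((5.0, 10.0, 10.0), (35.0, 10.0, 10.0), 2.0)
        out = hollow_airways(gray, tree, WallThicknessTable(ratios=(0.2,)), supersampling=5)
        profile = out.values[20, :, 10]
        # wall thinner than a voxel: measure each side's integrated material
        # (partial-volume mass), which must equal the 0.8 mm wall thickness
        # within half a voxel
        left = profile[:10].sum()
        right = profile[11:].sum()
        for side in (left, right):
            assert abs(side - 0.8) <= 0.5

    def test_lumen_center_zero_and_outer_boundary_kept(self):
        tree, gray = _tube((5.0, 10.0, 10.0), (35.0, 10.0, 10.0), 3.0)
        out = hollow_airways(gray, tree, WallThicknessTable(ratios=(0.2,)))
        assert out.values[20, 10, 10] == 0.0
        assert np.array_equal(out.values > 0, (out.values > 0) & (gray.values > 0))
        # outer geometry preserved: voxels beyond the tube stay empty,
        # surface partial voxels keep their gray
        surface = (gray.values > 0) & (gray.values < 0.5)
        assert np.allclose(out.values[surface], gray.values[surface])


class TestMapIntensities:
    def test_segment_mode_window_endpoints_and_midpoint(self):
        vals = np.zeros((5, 5, 5))
        vals[1, 1, 1] = 0.2
        vals[2, 2, 2] = 0.6
        vals[3, 3, 3] = 1.0
        out = map_intensities(VoxelGrid(vals), "segment", IntensityModel()).values
        assert out[1, 1, 1] == pytest.approx(35.0)
        assert out[2, 2, 2] == pytest.approx(40.0)
        assert out[3, 3, 3] == pytest.approx(45.0)
        assert out[0, 0, 0] == 0.0

    def test_anthro_mode_zero_sigma_gives_mean_exactly(self):
        vals = np.zeros((5, 5, 5))
        vals[2, 2, 2] = 1.0
        model = IntensityModel(mu_art=-42.0, sigma_art=0.0)
        out = map_intensities(
            VoxelGrid(vals), "anthro", model, "artery", np.random.default_rng(0)
        ).values
        assert out[2, 2, 2] == -42.0

    def test_all_zero_gray_passes_through(self):
        out = map_intensities(VoxelGrid(np.zeros((4, 4, 4))), "segment", IntensityModel())
        assert not out.values.any()


class TestDeformation:
    def _setup(self):
        tree, gray = _tube((5.0, 10.0, 10.0), (35.0, 10.0, 10.0), 2.0)
        mid = tree.add_child(tree.segment_ids[0], (35.0, 14.0, 10.0))
        tree.radius[mid] = 1.0
        grid = VoxelGrid(np.zeros((41, 21, 21)))
        gray, _ = rasterize_tree(tree, grid, supersampling=3)
        return {"gray": gray}, {"artery": tree}

    def test_zero_dmax_is_identity(self):
        volumes, trees = self._setup()
        out_v, out_t, field = deform_structures(
            volumes, trees, DeformationParams(deform_dmax=0.0, seed=1)
        )
        assert field is None
        assert np.array_equal(out_v["gray"].values, volumes["gray"].values)
        for nid in trees["artery"].node_ids:
            assert np.array_equal(
                out_t["artery"].positions[nid], trees["artery"].positions[nid]
            )

    def test_node_anchors_move_less_than_half_voxel(self):
        volumes, trees = self._setup()
        _, out_t, field = deform_structures(
            volumes, trees, DeformationParams(deform_dmax=3.0, seed=2)
        )
        for nid in trees["artery"].node_ids:
            moved = np.linalg.norm(
                out_t["artery"].positions[nid] - trees["artery"].positions[nid]
            )
            assert moved < 0.5

    def test_jacobian_positive_everywhere(self):
        """Numerical Jacobian oracle: central differences on a 2-voxel
        lattice; every determinant strictly positive (diffeomorphism)."""
        volumes, trees = self._setup()
        _, _, field = deform_structures(
            volumes, trees, DeformationParams(deform_dmax=3.0, seed=3)
        )
        dets = jacobian_determinants(field, volumes["gray"], step=2)
        assert np.all(dets > 0)

    def test_topology_preserved(self):
        volumes, trees = self._setup()
        _, out_t, _ = deform_structures(
            volumes, trees, DeformationParams(deform_dmax=3.0, seed=4)
        )
        assert out_t["artery"].node_ids == trees["artery"].node_ids
        assert out_t["artery"].parent == trees["artery"].parent


class TestComposePhantom:
    def _compose(self, noise):
        shape = (64, 64, 64)
        lung = VoxelGrid(np.ones(shape, dtype=np.uint8))
        hu = {"artery": lung.like(np.zeros(shape))}
        occ = {"artery": lung.like(np.zeros(shape))}
        return compose_phantom(hu, occ, lung, noise)

    def test_background_statistics(self):
        """Pre-blur background draws have mean -800 and SD 150 within
        sampling error at n >= 10^5 voxels."""
        comp = self._compose(NoiseParams(seed=7))
        bg = comp.pre_blur.values[comp.background_mask]
        n = bg.size
        assert n >= 1e5
        assert abs(bg.mean() + 800.0) < 3 * 150.0 / np.sqrt(n)
        sd = bg.std(ddof=1)
        assert abs(sd - 150.0) < 3 * 150.0 / np.sqrt(2 * (n - 1))

    def test_additive_noise_standard_deviation(self):
        comp = self._compose(NoiseParams(seed=8))
        resid = (comp.final.values - comp.pre_noise.values)[~comp.sp_mask]
        assert comp.sp_mask.sum() > 0
        assert resid.std() == pytest.approx(20.0, rel=0.02)

    def test_noise_free_final_equals_pre_noise_bitwise(self):
        comp = self._compose(NoiseParams(gauss_sd=0.0, sp_density=0.0, seed=9))
        assert np.array_equal(comp.final.values, comp.pre_noise.values)

    def test_seeded_reproducibility_bitwise(self):
        a = self._compose(NoiseParams(seed=10))
        b = self._compose(NoiseParams(seed=10))
        assert np.array_equal(a.final.values, b.final.values)


class TestEmbedPhantom:
    def _grids(self):
        host = VoxelGrid(np.full((9, 9, 9), 100.0))
        phantom = VoxelGrid(np.full((9, 9, 9), -500.0))
        mask = np.zeros((9, 9, 9), dtype=np.uint8)
        mask[3:6, 3:6, 3:6] = 1
        return host, VoxelGrid(mask), phantom

    def test_substitution_contract(self):
        host, mask, phantom = self._grids()
        out = embed_phantom(host, mask, phantom)
        m = mask.values > 0
        assert np.all(out.values[m] == phantom.values[m])
        assert np.all(out.values[~m] == host.values[~m])

    def test_empty_and_full_masks(self):
        host, mask, phantom = self._grids()
        empty = mask.like(np.zeros_like(mask.values))
        full = mask.like(np.ones_like(mask.values))
        assert np.array_equal(embed_phantom(host, empty, phantom).values, host.values)
        assert np.array_equal(embed_phantom(host, full, phantom).values, phantom.values)

    def test_shape_mismatch_rejected(self):
        host, mask, phantom = self._grids()
        small = VoxelGrid(np.zeros((5, 5, 5)))
        with pytest.raises(Exception):
            embed_phantom(host, mask, small)
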