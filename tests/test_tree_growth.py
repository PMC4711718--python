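"""Tree growth: hemodynamics, candidate sampling, attachment optimization."""

import math

import numpy as np
import pytest
from scipy import stats

from lungphantom import (
    GrowthExhaustedError,
    GrowthParams,
    Tree,
    VoxelGrid,
    airway_terminal_count,
    build_segment_artery_map,
    grow_tree,
    hemodynamic_update,
    optimal_attachment,
    oxygen_path_exists,
    sample_terminal_candidate,
    terminal_pressures,
    tree_cost,
)
from lungphantom.tree_growth import DegenerateCandidateError, _insert_bifurcation

MMHG = 133.322387415


class TestHemodynamics:
    def test_single_segment_poiseuille_closed_form(self, single_segment_tree, default_params):
        """r = (8 eta l Q / (pi dP))^(1/4) after SI conversion."""
        hemodynamic_update(single_segment_tree, default_params)
        eta = 36e-3
        length = 0.01
        q = 138.83 * 1e-6 / 60.0
        dp = 15.0 * MMHG
        expected_mm = (8 * eta * length * q / (math.pi * dp)) ** 0.25 * 1000.0
        seg = single_segment_tree.segment_ids[0]
        assert single_segment_tree.radius[seg] == pytest.approx(expected_mm, rel=1e-12)

    def test_symmetric_bifurcation_radius_ratio(self):
        """Equal child lengths and flows give r_child = r_parent * 2^(-1/gamma)."""
        t = Tree.with_root((0.0, 0.0, 0.0))
        mid = t.add_child(t.root_id, (10.0, 0.0, 0.0))
        t.add_child(mid, (20.0, 5.0, 0.0))
        t.add_child(mid, (20.0, -5.0, 0.0))
        p = GrowthParams(n_terminals=2)
        hemodynamic_update(t, p)
        kids = t.children[mid]
        assert t.radius[kids[0]] == pytest.approx(t.radius[kids[1]])
        assert t.radius[kids[0]] == pytest.approx(t.radius[mid] * 2 ** (-1 / p.gamma))

    def test_flow_conservation_exact_and_terminal_pressures(self, uniform_map):
        params = GrowthParams(n_terminals=12, p0=(5.0, 25.0, 25.0), seed=3)
        tree = grow_tree(uniform_map, params)
        for b in tree.bifurcation_ids:
            left, right = tree.children[b]
            assert tree.flow[b] == tree.flow[left] + tree.flow[right]
        pressures = np.array(list(terminal_pressures(tree, params).values()))
        assert np.allclose(pressures, params.p_fin, rtol=1e-6)

    def test_parent_radius_dominates_children(self, uniform_map):
        params = GrowthParams(n_terminals=15, p0=(5.0, 25.0, 25.0), seed=11)
        tree = grow_tree(uniform_map, params)
        for seg in tree.segment_ids:
            for child in tree.children[seg]:
                assert tree.radius[seg] >= tree.radius[child]


class TestCandidateSampling:
    def test_single_positive_voxel_always_chosen(self):
        vals = np.zeros((9, 9, 9))
        vals[2, 3, 4] = 0.7
        m = VoxelGrid(vals)
        rng = np.random.default_rng(0)
        tree = Tree.with_root((8.0, 8.0, 8.0))
        p = GrowthParams(n_terminals=1, p0=(8.0, 8.0, 8.0))
        for _ in range(5):
            pos = sample_terminal_candidate(m, tree, p, rng)
            assert np.allclose(pos, (2.0, 3.0, 4.0))

    def test_all_zero_map_raises_growth_exhausted(self):
        m = VoxelGrid(np.zeros((5, 5, 5)))
        with pytest.raises(GrowthExhaustedError):
            sample_terminal_candidate(
                m, None, GrowthParams(n_terminals=1), np.random.default_rng(0)
            )

    def test_uniform_map_sampling_is_uniform(self):
        """Chi-square goodness of fit of 10^4 unconstrained draws against
        the uniform law over 64 voxels (alpha = 0.01)."""
        m = VoxelGrid(np.ones((4, 4, 4)))
        rng = np.random.default_rng(123)
        p = GrowthParams(n_terminals=1, d_t=0.0)
        counts = np.zeros(64)
        for _ in range(10_000):
            pos = sample_terminal_candidate(m, None, p, rng)
            idx = tuple(int(round(c)) for c in pos)
            counts[np.ravel_multi_index(idx, (4, 4, 4))] += 1
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert stats.chi2.sf(chi2, df=63) > 0.01


class TestOxygenPath:
    def test_adjacent_positive_voxels_connected(self):
        m = VoxelGrid(np.ones((9, 9, 9)))
        tree = Tree.with_root((4.0, 4.0, 4.0))
        tree.add_child(tree.root_id, (6.0, 4.0, 4.0))
        assert oxygen_path_exists(m, (7.0, 5.0, 5.0), tree)

    def test_closed_zero_shell_blocks_path(self):
        """Flood-fill oracle: a zero-demand shell separates the candidate
        component from the tree component."""
        vals = np.ones((15, 15, 15))
        vals[9, :, :] = 0.0  # separating plane
        m = VoxelGrid(vals)
        tree = Tree.with_root((2.0, 7.0, 7.0))
        tree.add_child(tree.root_id, (5.0, 7.0, 7.0))
        assert not oxygen_path_exists(m, (12.0, 7.0, 7.0), tree)
        assert oxygen_path_exists(m, (7.0, 7.0, 7.0), tree)

    def test_zero_demand_candidate_is_disconnected(self):
        vals = np.ones((9, 9, 9))
        vals[6, 6, 6] = 0.0
        m = VoxelGrid(vals)
        tree = Tree.with_root((2.0, 2.0, 2.0))
        tree.add_child(tree.root_id, (4.0, 4.0, 4.0))
        assert not oxygen_path_exists(m, (6.0, 6.0, 6.0), tree)


class TestOptimalAttachment:
    def test_matches_exhaustive_grid_search(self, single_segment_tree, default_params):
        """Oracle: scan candidate bifurcation points along the segment at
        0.05*length steps; the optimizer must land within one step."""
        cand = np.array([10.0, 30.0, 25.0])
        plan = optimal_attachment(single_segment_tree, cand, None, default_params)
        ts = np.arange(0.05, 0.951, 0.05)
        costs = []
        for t in ts:
            trial = single_segment_tree.copy()
            _insert_bifurcation(trial, plan["segment"], t, cand)
            hemodynamic_update(trial, default_params)
            costs.append(tree_cost(trial, default_params))
        t_best = ts[int(np.argmin(costs))]
        assert abs(plan["t"] - t_best) <= 0.05 + 1e-9

    def test_k_larger_than_segment_count_is_fine(self, single_segment_tree, default_params):
        plan = optimal_attachment(
            single_segment_tree, (10.0, 28.0, 25.0), None, default_params
        )
        assert plan["segment"] in single_segment_tree.segment_ids

    def test_candidate_on_node_rejected(self, single_segment_tree, default_params):
        with pytest.raises(DegenerateCandidateError):
            optimal_attachment(
                single_segment_tree, (15.0, 25.0, 25.0), None, default_params
            )


class TestGrowTree:
    def test_single_terminal_tree(self, uniform_map):
        tree = grow_tree(uniform_map, GrowthParams(n_terminals=1, p0=(5, 25, 25), seed=2))
        assert tree.n_terminals == 1
        assert len(tree.bifurcation_ids) == 0
        assert tree.n_segments == 1

    def test_binary_counting_identity(self, uniform_map):
        tree = grow_tree(uniform_map, GrowthParams(n_terminals=10, p0=(5, 25, 25), seed=7))
        assert tree.n_terminals == 10
        assert len(tree.bifurcation_ids) == 9
        assert tree.n_segments == 19

    def test_determinism(self, uniform_map):
        params = GrowthParams(n_terminals=8, p0=(5, 25, 25), seed=99)
        a = grow_tree(uniform_map, params)
        b = grow_tree(uniform_map, params)
        assert a.node_ids == b.node_ids
        for nid in a.node_ids:
            assert np.array_equal(a.positions[nid], b.positions[nid])
        for seg in a.segment_ids:
            assert a.radius[seg] == b.radius[seg]

    def test_terminals_land_on_positive_demand(self):
        demand = build_segment_artery_map((41, 41, 41))
        params = GrowthParams(n_terminals=20, p0=(2.0, 20.0, 20.0), seed=5)
        tree = grow_tree(demand, params)
        good = sum(
            demand.values[demand.world_to_voxel(tree.positions[t])] > 0
            for t in tree.terminal_ids
        )
        assert good >= 0.95 * tree.n_terminals


@pytest.mark.parametrize(
    "n_art, fa, expected",
    [(50, 3, 17), (50, 1, 50), (30, 3, 10), (10, 4, 3), (1, 3, 1)],
)
def test_airway_terminal_count(n_art, fa, expected):
    assert airway_terminal_count(n_art, fa) == expected
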