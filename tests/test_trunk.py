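import numpy as np
import pytest

from canopyseg import (SegmentationParams, principal_direction,
                       find_seed_points, grow_trunk, extract_trunks,
                       branch_points, angle_between)
from canopyseg.skeleton import STATE_TRUNK, STATE_BRANCH


def power_iteration_direction(points, iters=200):
    """Independent dominant-eigenvector oracle."""
    pts = np.asarray(points, dtype=float)
    cov = np.cov(pts.T, bias=True)
    v = np.array([0.1, 0.2, 0.97])
    for _ in range(iters):
        v = cov @ v
        v /= np.linalg.norm(v)
    if v[2] < 0:
        v = -v
    return v


class TestPrincipalDirection:
    def test_vertical_line(self):
        pts = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2]], dtype=float)
        v, cov = principal_direction(pts)
        assert np.allclose(v, [0, 0, 1], atol=1e-12)
        assert cov.shape == (3, 3)

    def test_45_degree_line(self):
        t = np.linspace(0, 1, 5)
        pts = np.column_stack([t, np.zeros(5), t])
        v, _ = principal_direction(pts)
        assert np.allclose(v, [np.sqrt(2) / 2, 0, np.sqrt(2) / 2], atol=1e-12)

    def test_matches_power_iteration(self, rng):
        # anisotropic Gaussian cloud; angular agreement within 1e-6 rad
        axis = np.array([0.3, 0.2, 0.93])
        axis /= np.linalg.norm(axis)
        pts = (rng.normal(0, 3.0, (500, 1)) * axis[None, :]
               + rng.normal(0, 0.3, (500, 3)))
        v, _ = principal_direction(pts)
        w = power_iteration_direction(pts)
        angle = np.arccos(np.clip(abs(v @ w), -1, 1))
        assert angle < 1e-6

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            principal_direction(np.ones((5, 3)))

    def test_covariance_is_brute_force(self, rng):
        pts = rng.random((30, 3))
        _, cov = principal_direction(pts)
        centred = pts - pts.mean(axis=0)
        brute = sum(np.outer(c, c) for c in centred) / len(pts)
        assert np.allclose(cov, brute, atol=1e-12)


class TestAngleBetween:
    def test_orthogonal_and_zero(self):
        assert angle_between([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)
        assert angle_between([0, 0, 2], [0, 0, 5]) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            angle_between([0, 0, 0], [1, 0, 0])


def vertical_chain(x=0.0, y=0.0, top=5.0, dz=0.2):
    return [[x, y, z] for z in np.arange(0.1, top, dz)]


class TestFindSeedPoints:
    def test_single_tree_one_seed(self, skeleton_from_positions):
        sk = skeleton_from_positions(vertical_chain())
        traces = find_seed_points(sk, base_height=1.0, separation=1.0)
        assert len(traces) == 1
        assert sk.positions[traces[0].trunk_indices[0], 2] == pytest.approx(0.1)

    def test_close_stems_merge_and_flag(self, skeleton_from_positions):
        pts = [[0, 0, 0.1], [0.2, 0, 0.1], [3, 0, 0.1]]
        sk = skeleton_from_positions(pts)
        traces = find_seed_points(sk, base_height=1.0, separation=1.0)
        assert len(traces) == 2
        merged = [t for t in traces if t.ambiguous_seed]
        assert len(merged) == 1

    def test_no_low_skeleton_rejected(self, skeleton_from_positions):
        sk = skeleton_from_positions([[0, 0, 5.0]])
        with pytest.raises(ValueError):
            find_seed_points(sk, base_height=1.0)


class TestGrowTrunk:
    def test_sparse_vertical_chain_fully_classified(self,
                                                    skeleton_from_positions):
        sk = skeleton_from_positions(vertical_chain(top=4.0))
        params = SegmentationParams()
        traces = find_seed_points(sk, params.seed_base_height,
                                  params.seed_separation)
        trace = grow_trunk(traces[0], sk, params)
        states = sk.state[np.argsort(sk.positions[:, 2])]
        assert (states[:-1] == STATE_TRUNK).all()
        assert states[-1] == STATE_BRANCH  # chain end, nothing above
        assert trace.truncated  # ran out of candidates, not a density stop

    def test_angle_gate_rejects_oblique_candidate(self,
                                                  skeleton_from_positions):
        # chain up to 1.1 m, then a single candidate 30 deg off axis
        pts = vertical_chain(top=1.2)
        pts.append([0.3, 0.0, 1.62])  # ~30 deg from vertical over dz 0.52
        sk = skeleton_from_positions(pts)
        params = SegmentationParams(angle_tolerance=20.0)
        traces = find_seed_points(sk, params.seed_base_height,
                                  params.seed_separation)
        trace = grow_trunk(traces[0], sk, params)
        assert sk.state[-1] != STATE_TRUNK
        assert trace.branch_index is not None

    def test_gap_larger_than_search_radius_truncates(self,
                                                     skeleton_from_positions):
        pts = vertical_chain(top=2.0) + [[0, 0, 3.5], [0, 0, 3.7]]
        sk = skeleton_from_positions(pts)
        params = SegmentationParams(trunk_search_radius=0.6)
        traces = find_seed_points(sk, params.seed_base_height,
                                  params.seed_separation)
        trace = grow_trunk(traces[0], sk, params)
        assert trace.truncated
        assert sk.positions[trace.branch_index, 2] < 2.0

    def test_terminates_within_layer_budget(self, skeleton_from_positions):
        sk = skeleton_from_positions(vertical_chain(top=8.0))
        params = SegmentationParams()
        traces = find_seed_points(sk, params.seed_base_height,
                                  params.seed_separation)
        n_layers = int(sk.layer.max()) + 1
        trace = traces[0]
        from canopyseg.trunk import grow_step
        from scipy.spatial import cKDTree
        tree = cKDTree(sk.positions)
        steps = 0
        sizes = [len(trace.trunk_indices)]
        while grow_step(trace, sk, params, tree):
            steps += 1
            sizes.append(len(trace.trunk_indices))
            assert steps <= n_layers
        assert sizes == sorted(sizes)  # monotone growth


class TestPlotLevelTrunks:
    def test_branch_points_near_truth(self, small_plot):
        from canopyseg import build_skeleton, stand_crown_stats
        norm = small_plot["normalized"]
        specs = small_plot["specs"]
        params = SegmentationParams()
        sk = build_skeleton(norm, params)
        traces = extract_trunks(sk, params)
        assert len(traces) == len(specs)
        bp = branch_points(traces, sk)
        stems = np.array([s.stem_position for s in specs])
        for row in bp:
            k = int(np.argmin(np.hypot(stems[:, 0] - row[0],
                                       stems[:, 1] - row[1])))
            assert abs(row[2] - specs[k].branch_height) <= 0.4

    def test_trunk_points_below_branch_point(self, small_plot):
        from canopyseg import build_skeleton
        norm = small_plot["normalized"]
        params = SegmentationParams()
        sk = build_skeleton(norm, params)
        traces = extract_trunks(sk, params)
        for t in traces:
            bp_z = sk.positions[t.branch_index, 2]
            trunk_only = [i for i in t.trunk_indices if i != t.branch_index]
            assert (sk.positions[trunk_only, 2] <= bp_z).all()
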