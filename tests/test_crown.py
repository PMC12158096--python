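import numpy as np
import pytest

from canopyseg import (PointCloud, SegmentationParams, get_preset,
                       classify_crown_point, DisputeContext, resolve_disputed,
                       assign_boundary, segment_plot, build_skeleton,
                       backproject_labels, NO_LABEL)
from canopyseg.crown import CORE, BOUNDARY, DISPUTED, PERIPHERAL, DEFERRED
from canopyseg.skeleton import STATE_UNCLASSIFIED, STATE_DISPUTED


class TestClassifyCrownPoint:
    """Distance/density classification with the published low-closure values
    (T_HD1=1.5 m, T_HD2=5 m, rho2=4, rho3=11)."""

    params = get_preset("plotA")
    branch_xy = np.array([[0.0, 0.0], [6.0, 0.0]])

    def classify(self, d, rho):
        return classify_crown_point(np.array([d, 0.0, 8.0]), rho,
                                    self.branch_xy, self.params)

    def test_dense_inner_point_is_core(self):
        state, tree = self.classify(1.0, 12)
        assert state == CORE and tree == 0

    def test_sparse_annulus_point_is_boundary(self):
        state, tree = self.classify(3.0, 2)
        assert state == BOUNDARY and tree is None

    def test_mid_density_annulus_point_is_disputed(self):
        state, _ = self.classify(3.0, 7)
        assert state == DISPUTED

    def test_dense_annulus_point_is_peripheral(self):
        state, tree = self.classify(3.0, 15)
        assert state == PERIPHERAL and tree == 0

    def test_exact_t_hd1_takes_core_branch(self):
        state, tree = self.classify(1.5, 11)
        assert state == CORE and tree == 0

    def test_beyond_t_hd2_deferred(self):
        # x=5.5: 5.5 m from tree 0 but only 0.5 m from tree 1 -> core zone;
        # use a point far from both instead
        state, _ = classify_crown_point(np.array([20.0, 0.0, 8.0]), 12,
                                        self.branch_xy, self.params)
        assert state == DEFERRED

    def test_no_branch_points_rejected(self):
        with pytest.raises(ValueError):
            classify_crown_point(np.zeros(3), 5, np.empty((0, 2)), self.params)


def make_context(angles, distances):
    """DisputeContext with the given per-tree angles (deg) and distances."""
    return DisputeContext(
        disputed_index=0, position=np.zeros(3),
        neighbor_index={t: t for t in angles},
        neighbor_distance=dict(distances),
        growth_vector={t: np.array([0, 0, 1.0]) for t in angles},
        angle=dict(angles))


def oracle_resolve(angles, distances, threshold):
    """Exhaustive two-candidate arbitration oracle."""
    trees = sorted(angles)
    if not trees:
        return NO_LABEL
    if len(trees) >= 2:
        qual = [t for t in trees if angles[t] < threshold]
        if qual:
            best = min(angles[t] for t in qual)
            winners = [t for t in qual if abs(angles[t] - best) < 1e-9]
            if len(winners) == 1:
                return winners[0]
    # fallback: nearest distance, lower id on ties
    dmin = min(distances[t] for t in trees)
    return min(t for t in trees if abs(distances[t] - dmin) < 1e-9)


class TestResolveDisputed:
    def test_smaller_angle_wins(self):
        ctx = make_context({1: 30.0, 2: 70.0}, {1: 0.5, 2: 0.3})
        assert resolve_disputed(ctx, 60.0) == 1

    def test_both_over_threshold_falls_back_to_distance(self):
        ctx = make_context({1: 75.0, 2: 80.0}, {1: 0.5, 2: 0.3})
        assert resolve_disputed(ctx, 60.0) == 2

    def test_equal_angles_fall_back_to_distance(self):
        ctx = make_context({1: 40.0, 2: 40.0}, {1: 0.5, 2: 0.3})
        assert resolve_disputed(ctx, 60.0) == 2

    def test_no_neighbours_unresolvable(self):
        ctx = make_context({}, {})
        assert resolve_disputed(ctx, 60.0) == NO_LABEL

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(300):
            n = rng.integers(1, 4)
            trees = list(rng.choice(10, size=n, replace=False))
            angles = {int(t): float(rng.uniform(0, 180)) for t in trees}
            dists = {int(t): float(rng.uniform(0.1, 1.0)) for t in trees}
            thr = float(rng.choice([50.0, 60.0]))
            ctx = make_context(angles, dists)
            assert resolve_disputed(ctx, thr) == oracle_resolve(angles, dists,
                                                                thr)


class TestAssignBoundary:
    def test_single_tree(self):
        pos = np.array([0.0, 0.0, 5.0])
        cls = np.array([[1.0, 0.0, 5.0]])
        assert assign_boundary(pos, cls, np.array([3])) == 3

    def test_equidistant_breaks_to_lower_id(self):
        pos = np.zeros(3)
        cls = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert assign_boundary(pos, cls, np.array([7, 2])) == 2

    def test_matches_pairwise_oracle(self, rng):
        cls = rng.random((40, 3)) * 5
        ids = rng.integers(0, 6, 40)
        for _ in range(50):
            pos = rng.random(3) * 5
            got = assign_boundary(pos, cls, ids)
            d = np.linalg.norm(cls - pos, axis=1)
            near = ids[d <= d.min() + 1e-9]
            assert got == near.min()


class TestSegmentPlot:
    def test_empty_vegetation_gives_empty_result(self):
        cloud = PointCloud(xyz=np.empty((0, 3)), height=np.empty(0))
        result = segment_plot(cloud)
        assert result.instances == []
        assert len(result.labels) == 0

    def test_single_isolated_tree(self, single_tree_spec, rng):
        from canopyseg import generate_tree
        xyz, part = generate_tree(single_tree_spec, 500.0, rng)
        cloud = PointCloud(xyz=xyz, height=xyz[:, 2], part=part)
        result = segment_plot(cloud)
        assert len(result.instances) == 1
        assert (result.labels >= 0).all()
        assert not (result.skeleton.state == STATE_DISPUTED).any()

    def test_every_skeleton_point_classified_exactly_once(self, small_plot):
        result = segment_plot(small_plot["normalized"])
        sk = result.skeleton
        assert not (sk.state == STATE_UNCLASSIFIED).any()
        assert (sk.tree_id >= 0).all()

    def test_labels_cover_all_vegetation(self, small_plot):
        norm = small_plot["normalized"]
        result = segment_plot(norm)
        veg = ~np.asarray(norm.ground)
        assert (result.labels[veg] >= 0).all()
        assert (result.labels[~veg] == NO_LABEL).all()

    def test_point_counts_conserved(self, small_plot):
        norm = small_plot["normalized"]
        result = segment_plot(norm)
        sk = result.skeleton
        total = sum(len(m) for m in sk.members) + len(sk.noise_indices)
        assert sum(i.n_points for i in result.instances) == total

    def test_point_level_accuracy_on_low_closure(self, small_plot):
        from canopyseg import stand_crown_stats
        norm = small_plot["normalized"]
        rmin, rmax, aspect = stand_crown_stats(small_plot["specs"])
        result = segment_plot(norm,
                              SegmentationParams(crown_aspect=aspect),
                              calibration_radii=(rmin, rmax))
        # map predicted ids to truth ids via the seed stems
        specs = small_plot["specs"]
        stems = np.array([s.stem_position for s in specs])
        mapping = {}
        for inst in result.instances:
            k = int(np.argmin(np.hypot(stems[:, 0] - inst.branch_point[0],
                                       stems[:, 1] - inst.branch_point[1])))
            mapping[inst.tree_id] = k
        veg = (~np.asarray(norm.ground)) & (norm.truth_id >= 0)
        pred_truth = np.array([mapping.get(t, -9)
                               for t in result.labels[veg]])
        accuracy = (pred_truth == norm.truth_id[veg]).mean()
        assert accuracy >= 0.95

    def test_backprojection_requires_labels(self, small_plot):
        norm = small_plot["normalized"]
        sk = build_skeleton(norm, SegmentationParams())
        with pytest.raises(ValueError, match="unlabelled"):
            backproject_labels(sk, norm)

    def test_manifest_shape(self, small_plot):
        result = segment_plot(small_plot["normalized"])
        manifest = result.manifest()
        assert len(manifest) == len(result.instances)
        assert {"tree_id", "branch_height", "n_points"} <= manifest[0].keys()
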