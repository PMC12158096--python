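import numpy as np
import pytest

from canopyseg import (PlotSpec, TreeSpec, TreeVariation, generate_plantation,
                       preprocess)


@pytest.fixture(scope="session")
def small_plot():
    """A fast 2x3-tree plot with ground truth, raw and normalized clouds."""
    plot = PlotSpec(n_rows=2, n_cols=3, tree_spacing=3.0, row_spacing=7.0,
                    target_point_density=500.0, rng_seed=7)
    variation = TreeVariation(crown_radius_mean=1.4, crown_aspect=1.4)
    cloud, specs = generate_plantation(plot, variation)
    normalized, dem = preprocess(cloud)
    return {"plot": plot, "variation": variation, "cloud": cloud,
            "specs": specs, "normalized": normalized, "dem": dem}


@pytest.fixture
def single_tree_spec():
    return TreeSpec(stem_position=(0.0, 0.0), tree_height=12.0,
                    branch_height=5.0, crown_radius_ew=2.0,
                    crown_radius_ns=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def skeleton_from_positions():
    """Factory building a Skeleton with one point per given 3D position."""
    from canopyseg import PointCloud, SegmentationParams, build_skeleton

    def build(positions):
        positions = np.asarray(positions, dtype=float)
        cloud = PointCloud(xyz=positions, height=positions[:, 2])
        return build_skeleton(cloud, SegmentationParams(dbscan_min_pts=1,
                                                        dbscan_eps=0.01))

    return build
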