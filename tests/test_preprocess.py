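import numpy as np
import pytest
from scipy.spatial import cKDTree

from canopyseg import (PointCloud, remove_outliers, classify_ground,
                       build_dem_idw, normalize_heights, preprocess,
                       DEMRaster)


def _grid_cloud(n=15, spacing=1.0, z=0.0):
    xx, yy = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    return PointCloud(xyz=np.column_stack(
        [xx.ravel(), yy.ravel(), np.full(n * n, z)]))


class TestRemoveOutliers:
    def test_displaced_point_removed(self, rng):
        # dense 1 m cluster plus one point displaced 50 m
        pts = rng.normal(0, 0.3, (300, 3))
        pts = np.vstack([pts, [[50.0, 0.0, 0.0]]])
        cloud = PointCloud(xyz=pts)
        clean, removed = remove_outliers(cloud, k_neighbors=8, sigma_mult=3.0)
        assert removed[-1]
        assert removed.sum() == 1
        # cross-check against brute-force mean k-NN distances
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        mean_knn = np.sort(d, axis=1)[:, :8].mean(axis=1)
        thr = mean_knn.mean() + 3.0 * mean_knn.std()
        assert np.array_equal(removed, mean_knn > thr)

    def test_infinite_sigma_is_identity(self, rng):
        cloud = PointCloud(xyz=rng.random((50, 3)))
        clean, removed = remove_outliers(cloud, sigma_mult=np.inf)
        assert len(clean) == 50 and not removed.any()

    def test_equal_neighbourhoods_keep_everything(self):
        # points equally spaced on a ring: every mean k-NN distance is
        # identical, so nothing can exceed mean + 3 sd
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        ring = PointCloud(xyz=np.column_stack(
            [10 * np.cos(t), 10 * np.sin(t), np.zeros(100)]))
        clean, removed = remove_outliers(ring, k_neighbors=8, sigma_mult=3.0)
        assert not removed.any()

    def test_bad_k_rejected(self, rng):
        with pytest.raises(ValueError):
            remove_outliers(PointCloud(xyz=rng.random((20, 3))), k_neighbors=0)


class TestClassifyGround:
    def test_flat_plane_plus_tree(self, rng):
        plane = np.column_stack([rng.uniform(0, 10, 2000),
                                 rng.uniform(0, 10, 2000),
                                 np.zeros(2000)])
        trunk = np.column_stack([np.full(200, 5.0) + rng.normal(0, 0.05, 200),
                                 np.full(200, 5.0) + rng.normal(0, 0.05, 200),
                                 rng.uniform(0.5, 8.0, 200)])
        cloud = PointCloud(xyz=np.vstack([plane, trunk]))
        flags = classify_ground(cloud, cell=1.0, height_tol=0.15)
        assert flags[:2000].all()
        assert not flags[2000:].any()

    def test_floating_canopy_mostly_unflagged(self, rng):
        # a canopy slab with no true ground: only returns hugging the
        # per-cell minimum surface can be flagged, everything clearly
        # above it must not be
        z = rng.uniform(3.0, 8.0, 300)
        xyz = np.column_stack([rng.uniform(0, 5, 300),
                               rng.uniform(0, 5, 300), z])
        flags = classify_ground(PointCloud(xyz=xyz), cell=5.0, height_tol=0.15)
        assert not flags[z > 3.5].any()
        assert flags.mean() < 0.1

    def test_rough_plane_recovered(self):
        # simulator terrain with 5 cm roughness and no outlier returns
        from canopyseg import PlotSpec, TreeVariation, generate_plantation
        plot = PlotSpec(n_rows=1, n_cols=2, target_point_density=400.0,
                        noise_fraction=0.0, ground_roughness=0.05, rng_seed=2)
        cloud, _ = generate_plantation(plot, TreeVariation())
        flags = classify_ground(cloud, cell=1.0, height_tol=0.15)
        truth = np.asarray(cloud.ground)
        recovered = (flags & truth).sum() / truth.sum()
        assert recovered >= 0.99

    def test_empty_cloud(self):
        with pytest.raises(ValueError):
            classify_ground(PointCloud(xyz=np.empty((0, 3))))


class TestBuildDemIdw:
    def test_constant_field(self, rng):
        pts = np.column_stack([rng.uniform(0, 10, 500),
                               rng.uniform(0, 10, 500),
                               np.full(500, 100.0)])
        dem = build_dem_idw(pts, cell=0.5, radius=1.5)
        assert np.allclose(dem.values, 100.0)

    def test_single_point(self):
        dem = build_dem_idw(np.array([[1.0, 1.0, 42.0]]), cell=0.5, radius=1.5)
        assert np.allclose(dem.values, 42.0)

    def test_two_point_idw_closed_form(self):
        # query equidistant from elevations 0 and 10 -> 5 with power 2
        pts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 10.0]])
        dem = build_dem_idw(pts, cell=1.0, power=2.0, radius=5.0)
        # cell centre at (0.5, 0.5) is equidistant from both points
        centre_val = dem.lookup(np.array([0.5]), np.array([0.5]))
        assert centre_val[0] == pytest.approx(5.0, abs=1e-9)

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            build_dem_idw(np.array([[0, 0, 1.0]]), radius=0.0)

    def test_fallback_cells_flagged(self):
        pts = np.array([[0.0, 0.0, 1.0], [8.0, 8.0, 3.0]])
        dem = build_dem_idw(pts, cell=1.0, radius=1.0)
        assert dem.fallback.any()
        assert np.isfinite(dem.values).all()

    def test_ascii_export(self, tmp_path):
        dem = build_dem_idw(np.array([[0, 0, 1.0], [2, 2, 3.0]]),
                            cell=1.0, radius=5.0)
        out = tmp_path / "dem.asc"
        dem.write_ascii(out)
        text = out.read_text()
        assert "ncols" in text and "cellsize 1.000" in text


class TestNormalizeHeights:
    def _flat_dem(self, elevation, size=10, cell=1.0):
        n = int(size / cell)
        return DEMRaster(origin=(0.0, 0.0), cell_size=cell,
                         values=np.full((n, n), float(elevation)),
                         fallback=np.zeros((n, n), dtype=bool))

    def test_flat_dem(self):
        cloud = PointCloud(xyz=np.array([[5.0, 5.0, 112.0], [2.0, 2.0, 100.0]]))
        out = normalize_heights(cloud, self._flat_dem(100.0))
        assert out.height[0] == pytest.approx(12.0)
        assert out.height[1] == pytest.approx(0.0)

    def test_tilted_plane_normalizes_to_zero(self, rng):
        x = rng.uniform(0.5, 9.5, 800)
        y = rng.uniform(0.5, 9.5, 800)
        z = 50.0 + 0.1 * x + 0.05 * y
        ground = PointCloud(xyz=np.column_stack([x, y, z]))
        dem = build_dem_idw(ground, cell=0.5, radius=1.5)
        out = normalize_heights(ground, dem)
        assert np.quantile(np.abs(out.height), 0.99) < 0.05

    def test_point_outside_dem_rejected(self):
        cloud = PointCloud(xyz=np.array([[50.0, 50.0, 1.0]]))
        with pytest.raises(ValueError, match="outside"):
            normalize_heights(cloud, self._flat_dem(0.0))

    def test_deep_negative_rejected(self):
        cloud = PointCloud(xyz=np.array([[5.0, 5.0, 99.0]]))
        with pytest.raises(ValueError, match="below the DEM"):
            normalize_heights(cloud, self._flat_dem(100.0))

    def test_idempotent_against_zero_dem(self, rng):
        xyz = np.column_stack([rng.uniform(0, 9, 100),
                               rng.uniform(0, 9, 100),
                               rng.uniform(0, 5, 100)])
        dem = self._flat_dem(0.0)
        once = normalize_heights(PointCloud(xyz=xyz), dem)
        twice = normalize_heights(once, dem)
        assert np.array_equal(once.height, twice.height)


class TestPipeline:
    def test_ground_heights_within_tolerance(self, small_plot):
        norm = small_plot["normalized"]
        gh = norm.height[np.asarray(norm.ground)]
        assert np.quantile(gh, 0.99) < 0.15

    def test_outlier_removal_bounded_by_noise_fraction(self, small_plot):
        cloud = small_plot["cloud"]
        _, removed = remove_outliers(cloud, k_neighbors=8, sigma_mult=3.0)
        assert removed.mean() <= small_plot["plot"].noise_fraction + 0.01
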