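"""Cloud cleaning and height normalization.

The segmentation method operates on noise-free, height-normalized vegetation
points.  This module provides the standard chain: statistical outlier
removal, a grid-minimum ground filter (pre-classified ground flags may be
supplied instead), an inverse-distance-weighted ground DEM, and per-point
height normalization against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.interpolate import RegularGridInterpolator

from .cloud import PointCloud


def remove_outliers(cloud: PointCloud, k_neighbors: int = 8,
                    sigma_mult: float = 3.0) -> tuple[PointCloud, np.ndarray]:
    """Statistical outlier removal on mean k-nearest-neighbour distance.

    A point is removed when its mean distance to its ``k_neighbors`` nearest
    neighbours exceeds the global mean by more than ``sigma_mult`` standard
    deviations.  Returns ``(clean_cloud, removed_mask)``.
    """
    if k_neighbors <= 0:
        raise ValueError("k_neighbors must be positive")
    n = len(cloud)
    if n < k_neighbors + 1:
        raise ValueError(f"need at least {k_neighbors + 1} points, got {n}")
    tree = cKDTree(cloud.xyz)
    dist, _ = tree.query(cloud.xyz, k=k_neighbors + 1)
    mean_d = dist[:, 1:].mean(axis=1)  # drop self-distance
    if np.isinf(sigma_mult):
        removed = np.zeros(n, dtype=bool)
    else:
        thresh = mean_d.mean() + sigma_mult * mean_d.std()
        removed = mean_d > thresh
    return cloud.subset(~removed), removed


def classify_ground(cloud: PointCloud, cell: float = 1.0,
                    height_tol: float = 0.15) -> np.ndarray:
    """Grid-minimum ground filter; returns a per-point boolean flag.

    The lowest return in each ``cell`` x ``cell`` column seeds a ground
    surface; the seed elevations are interpolated bilinearly (nearest-filled
    outside the seeded region) and every point within ``height_tol`` of that
    surface is flagged as ground.  This is a deliberately simple stand-in
    for heavier ground classifiers — plantation terrain is close to planar —
    and is bypassed entirely when pre-classified flags are available.
    """
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    if cell <= 0:
        raise ValueError("cell must be positive")
    x, y, z = cloud.x, cloud.y, cloud.z
    x0, y0 = float(x.min()), float(y.min())
    nx = max(1, int(np.ceil((x.max() - x0) / cell)) + 1)
    ny = max(1, int(np.ceil((y.max() - y0) / cell)) + 1)
    ix = np.minimum(((x - x0) / cell).astype(np.int64), nx - 1)
    iy = np.minimum(((y - y0) / cell).astype(np.int64), ny - 1)
    flat = ix * ny + iy
    zmin = np.full(nx * ny, np.inf)
    np.minimum.at(zmin, flat, z)
    zmin = zmin.reshape(nx, ny)

    # fill unseeded cells from the nearest seeded cell
    seeded = np.isfinite(zmin)
    if not seeded.any():
        raise ValueError("no cells could be seeded")
    if not seeded.all():
        si, sj = np.nonzero(seeded)
        ui, uj = np.nonzero(~seeded)
        t = cKDTree(np.column_stack([si, sj]))
        _, nn = t.query(np.column_stack([ui, uj]))
        zmin[ui, uj] = zmin[si[nn], sj[nn]]

    # smooth bilinear surface through the cell-minimum grid
    gx = x0 + (np.arange(nx) + 0.5) * cell
    gy = y0 + (np.arange(ny) + 0.5) * cell
    interp = RegularGridInterpolator((gx, gy), zmin, bounds_error=False,
                                     fill_value=None)
    qx = np.clip(x, gx[0], gx[-1])
    qy = np.clip(y, gy[0], gy[-1])
    surf = interp(np.column_stack([qx, qy]))
    return (z - surf) <= height_tol


@dataclass
class DEMRaster:
    """Regular ground-elevation grid.

    ``values[i, j]`` is the elevation at cell centre
    ``origin + ((i + 0.5) * cell_size, (j + 0.5) * cell_size)``;
    ``fallback[i, j]`` marks cells that had no ground point within the IDW
    search radius and were filled from the nearest ground point.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    fallback: np.ndarray

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        nx, ny = self.values.shape
        return (self.origin[0], self.origin[1],
                self.origin[0] + nx * self.cell_size,
                self.origin[1] + ny * self.cell_size)

    def lookup(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear elevation lookup (edge cells extend beyond centres)."""
        nx, ny = self.values.shape
        gx = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        gy = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        if nx == 1 and ny == 1:
            return np.full(np.shape(x), self.values[0, 0], dtype=float)
        x0, y0, x1, y1 = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        outside = (x < x0 - 1e-9) | (x > x1 + 1e-9) | (y < y0 - 1e-9) | (y > y1 + 1e-9)
        if outside.any():
            idx = np.nonzero(outside)[0][:10]
            raise ValueError(f"{int(outside.sum())} points outside DEM extent, "
                             f"first offenders at indices {idx.tolist()}")
        if nx == 1 or ny == 1:
            vals = self.values[0, :] if nx == 1 else self.values[:, 0]
            g = gy if nx == 1 else gx
            q = np.clip(y if nx == 1 else x, g[0], g[-1])
            return np.interp(q, g, vals)
        interp = RegularGridInterpolator((gx, gy), self.values,
                                         bounds_error=False, fill_value=None)
        qx = np.clip(x, gx[0], gx[-1])
        qy = np.clip(y, gy[0], gy[-1])
        return interp(np.column_stack([qx, qy]))

    def write_ascii(self, path: str | Path) -> None:
        """Write an ESRI ASCII-grid style text raster."""
        nx, ny = self.values.shape
        lines = [f"ncols {nx}", f"nrows {ny}",
                 f"xllcorner {self.origin[0]:.3f}", f"yllcorner {self.origin[1]:.3f}",
                 f"cellsize {self.cell_size:.3f}", "NODATA_value -9999"]
        # rows top-down, as in the ASCII grid convention
        grid = self.values.T[::-1]
        for row in grid:
            lines.append(" ".join(f"{v:.3f}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


def build_dem_idw(ground: PointCloud | np.ndarray, cell: float = 0.5,
                  power: float = 2.0, radius: float = 1.5) -> DEMRaster:
    """Inverse-distance-weighted ground DEM (default power 2, radius 1.5 m).

    Each cell centre takes the IDW mean of ground elevations within
    ``radius``; cells with no ground point in range fall back to the nearest
    ground point's elevation and are flagged.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if cell <= 0:
        raise ValueError("cell must be positive")
    pts = ground.xyz if isinstance(ground, PointCloud) else np.asarray(ground, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValueError("need at least one ground point with x, y, z")
    x0, y0 = float(pts[:, 0].min()), float(pts[:, 1].min())
    nx = max(1, int(np.ceil((pts[:, 0].max() - x0) / cell)) + 1)
    ny = max(1, int(np.ceil((pts[:, 1].max() - y0) / cell)) + 1)
    cx = x0 + (np.arange(nx) + 0.5) * cell
    cy = y0 + (np.arange(ny) + 0.5) * cell
    centres = np.column_stack([np.repeat(cx, ny), np.tile(cy, nx)])

    tree = cKDTree(pts[:, :2])
    neighbours = tree.query_ball_point(centres, r=radius)
    values = np.empty(nx * ny)
    fallback = np.zeros(nx * ny, dtype=bool)
    for i, idx in enumerate(neighbours):
        if not idx:
            fallback[i] = True
            continue
        d = np.hypot(pts[idx, 0] - centres[i, 0], pts[idx, 1] - centres[i, 1])
        exact = d < 1e-9
        if exact.any():
            values[i] = pts[np.asarray(idx)[exact][0], 2]
        else:
            w = 1.0 / d ** power
            values[i] = float(np.average(pts[idx, 2], weights=w))
    if fallback.any():
        _, nn = tree.query(centres[fallback])
        values[fallback] = pts[nn, 2]
    return DEMRaster(origin=(x0, y0), cell_size=cell,
                     values=values.reshape(nx, ny),
                     fallback=fallback.reshape(nx, ny))


def normalize_heights(cloud: PointCloud, dem: DEMRaster,
                      clamp_tol: float = 0.05) -> PointCloud:
    """Replace z by height above the DEM (bilinear lookup).

    Normalized heights in ``[-clamp_tol, 0)`` — DEM interpolation jitter —
    are clamped to zero; larger negatives raise, since they indicate a wrong
    DEM rather than jitter.  The result keeps the original z in ``xyz`` and
    stores the normalized value in the ``height`` column.
    """
    h = cloud.z - dem.lookup(cloud.x, cloud.y)
    bad = h < -clamp_tol
    if bad.any():
        idx = np.nonzero(bad)[0][:10]
        raise ValueError(
            f"{int(bad.sum())} points more than {clamp_tol} m below the DEM "
            f"(first indices {idx.tolist()}); check ground classification")
    return cloud.with_(height=np.maximum(h, 0.0))


def preprocess(cloud: PointCloud, k_neighbors: int = 8, sigma_mult: float = 3.0,
               ground_cell: float = 1.0, height_tol: float = 0.15,
               dem_cell: float = 0.5, idw_power: float = 2.0,
               idw_radius: float = 1.5,
               use_ground_flags: bool = True) -> tuple[PointCloud, DEMRaster]:
    """Full cleaning chain: denoise, ground-classify, DEM, normalize.

    Returns the denoised cloud (with ``ground`` flags and normalized
    ``height``) and the DEM.  Pre-existing ``ground`` flags are honoured
    when ``use_ground_flags`` is set.  Points more than 0.05 m below the
    DEM — residual low outliers that survived statistical denoising — are
    dropped rather than propagated.
    """
    clean, _ = remove_outliers(cloud, k_neighbors=k_neighbors,
                               sigma_mult=sigma_mult)
    if use_ground_flags and clean.ground is not None:
        gmask = np.asarray(clean.ground, dtype=bool)
    else:
        gmask = classify_ground(clean, cell=ground_cell, height_tol=height_tol)
    if not gmask.any():
        raise ValueError("no ground points found; cannot build a DEM")
    dem = build_dem_idw(clean.subset(gmask), cell=dem_cell,
                        power=idw_power, radius=idw_radius)
    x0, y0, x1, y1 = dem.extent
    inside = ((clean.x >= x0) & (clean.x <= x1)
              & (clean.y >= y0) & (clean.y <= y1))
    clean = clean.with_(ground=gmask).subset(inside)
    h = clean.z - dem.lookup(clean.x, clean.y)
    normalized = normalize_heights(clean.subset(h >= -0.05), dem)
    return normalized, dem
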