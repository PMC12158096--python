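"""Initial skeleton points: per-layer density clusters and their centroids.

The normalized vegetation cloud is cut into horizontal slabs of thickness
ΔHL (0.2 m by default), each slab is clustered with DBSCAN in the horizontal
plane, and every cluster is compressed to its centroid — a *skeleton point*.
Skeleton points carry their member raw-point indices, a local density
(neighbouring skeleton points within a fixed radius), and a classification
state that the trunk and crown stages fill in.  Clustering within a slab is
planar (xy): with a 0.2 m slab, z is nearly constant and planar clustering
keeps the eps semantics stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .cloud import PointCloud, NO_LABEL
from .params import SegmentationParams

# classification states of a skeleton point
STATE_UNCLASSIFIED = 0
STATE_TRUNK = 1
STATE_BRANCH = 2      # the trunk/canopy transition point of a trace
STATE_CORE = 3
STATE_BOUNDARY = 4
STATE_DISPUTED = 5
STATE_PERIPHERAL = 6  # high-density crown point outside the core zone

STATE_NAMES = {
    STATE_UNCLASSIFIED: "unclassified", STATE_TRUNK: "trunk",
    STATE_BRANCH: "branch", STATE_CORE: "core", STATE_BOUNDARY: "boundary",
    STATE_DISPUTED: "disputed", STATE_PERIPHERAL: "peripheral",
}


def slice_layers(heights: np.ndarray, layer_thickness: float,
                 tol: float = 1e-6) -> np.ndarray:
    """Assign each height to half-open layer ``[i*ΔHL, (i+1)*ΔHL)``."""
    if layer_thickness <= 0:
        raise ValueError("layer_thickness must be positive")
    h = np.asarray(heights, dtype=float)
    if (h < -tol).any():
        raise ValueError("negative normalized heights present; "
                         "normalize the cloud first")
    return np.floor(np.maximum(h, 0.0) / layer_thickness).astype(np.int64)


def cluster_layer(xy: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """DBSCAN labels for one layer's points (-1 = noise)."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) == 0:
        raise ValueError("layer is empty")
    if len(xy) < min_pts:
        return np.full(len(xy), -1, dtype=np.int64)
    return DBSCAN(eps=eps, min_samples=min_pts).fit(xy).labels_.astype(np.int64)


def layer_centroids(points: np.ndarray, labels: np.ndarray
                    ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Centroid and member-index list per non-noise cluster."""
    labels = np.asarray(labels)
    ids = np.unique(labels[labels >= 0])
    if len(ids) == 0:
        return np.empty((0, 3)), []
    centroids = np.empty((len(ids), 3))
    members: list[np.ndarray] = []
    for k, cid in enumerate(ids):
        idx = np.nonzero(labels == cid)[0]
        if len(idx) == 0:
            raise ValueError("empty cluster")
        centroids[k] = points[idx].mean(axis=0)
        members.append(idx)
    return centroids, members


@dataclass
class Skeleton:
    """Array-of-structs container for all skeleton points of a plot.

    ``members[i]`` indexes into the cloud the skeleton was built from;
    ``noise_indices`` are vegetation points DBSCAN rejected (re-attached at
    back-projection).  ``positions[:, 2]`` is in normalized-height space.
    """

    positions: np.ndarray                      # (M, 3), z = normalized height
    layer: np.ndarray                          # (M,) int
    cluster_id: np.ndarray                     # (M,) within-layer cluster id
    members: list[np.ndarray]
    noise_indices: np.ndarray
    density: np.ndarray = field(default=None)  # type: ignore[assignment]
    state: np.ndarray = field(default=None)    # type: ignore[assignment]
    tree_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = len(self.positions)
        if self.density is None:
            self.density = np.zeros(m, dtype=np.int64)
        if self.state is None:
            self.state = np.full(m, STATE_UNCLASSIFIED, dtype=np.int8)
        if self.tree_id is None:
            self.tree_id = np.full(m, NO_LABEL, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def member_counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.members], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.positions[:, 0], "y": self.positions[:, 1],
            "z": self.positions[:, 2], "layer": self.layer,
            "cluster": self.cluster_id, "n_members": self.member_counts,
            "density": self.density,
            "state": [STATE_NAMES[s] for s in self.state],
            "tree_id": self.tree_id,
        })

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.4f")


def build_skeleton(cloud: PointCloud, params: SegmentationParams | None = None,
                   vegetation_mask: np.ndarray | None = None) -> Skeleton:
    """Slice, cluster and compress a normalized cloud into a Skeleton.

    ``cloud.height`` must be present.  Vegetation points default to the
    non-ground points (or all points when no ground flags exist); member and
    noise indices refer to positions in ``cloud``.  Skeleton z coordinates
    are mean member normalized heights, so the whole downstream pipeline
    works in height-above-ground space.
    """
    params = params or SegmentationParams()
    if cloud.height is None:
        raise ValueError("cloud has no normalized heights; run preprocessing")
    if vegetation_mask is None:
        if cloud.ground is not None:
            vegetation_mask = ~np.asarray(cloud.ground, dtype=bool)
        else:
            vegetation_mask = np.ones(len(cloud), dtype=bool)
    veg_idx = np.nonzero(vegetation_mask)[0]
    h = cloud.height[veg_idx]
    xy = cloud.xyz[veg_idx, :2]
    layers = slice_layers(h, params.layer_thickness)

    positions, layer_out, cluster_out, members = [], [], [], []
    noise: list[np.ndarray] = []
    for li in np.unique(layers):
        sel = np.nonzero(layers == li)[0]
        labels = cluster_layer(xy[sel], params.dbscan_eps, params.dbscan_min_pts)
        pts3 = np.column_stack([xy[sel], h[sel]])
        cent, mem = layer_centroids(pts3, labels)
        noise.append(veg_idx[sel[labels < 0]])
        for k, m in enumerate(mem):
            positions.append(cent[k])
            layer_out.append(li)
            cluster_out.append(k)
            members.append(veg_idx[sel[m]])

    positions = np.asarray(positions) if positions else np.empty((0, 3))
    skel = Skeleton(
        positions=positions,
        layer=np.asarray(layer_out, dtype=np.int64),
        cluster_id=np.asarray(cluster_out, dtype=np.int64),
        members=members,
        noise_indices=(np.concatenate(noise) if noise
                       else np.empty(0, dtype=np.int64)),
    )
    if len(skel):
        skel.density = compute_local_density(skel, params.density_radius)
    return skel


def compute_local_density(skeleton: Skeleton, radius: float) -> np.ndarray:
    """Count of *other* skeleton points within a 3D ``radius`` of each one."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(skeleton) == 0:
        return np.empty(0, dtype=np.int64)
    tree = cKDTree(skeleton.positions)
    counts = tree.query_ball_point(skeleton.positions, r=radius,
                                   return_length=True)
    return np.asarray(counts, dtype=np.int64) - 1
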