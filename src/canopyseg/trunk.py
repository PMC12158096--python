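"""Bottom-up trunk extraction and branch-point detection.

Each trunk trace starts from a seed — the lowest skeleton point of a
spatially separated trunk-base group — and grows upward one skeleton point
at a time.  A candidate joins the trunk when (a) the step from the current
frontier to the candidate deviates from the trace's principal direction by
less than the angle tolerance and (b) the candidate's neighbourhood holds
fewer unclassified skeleton points than the branch-density threshold ρ1.
The principal direction is refreshed after every step from the covariance of
the grown trunk plus the current candidate set.  When no candidate passes
both tests the frontier is the *branch point* — the trunk/canopy transition
— and the trace terminates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import NO_LABEL
from .params import SegmentationParams
from .skeleton import Skeleton, STATE_UNCLASSIFIED, STATE_TRUNK, STATE_BRANCH

UP = np.array([0.0, 0.0, 1.0])


def principal_direction(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dominant eigenvector of the centred covariance, pointing upward.

    Returns ``(unit_direction, covariance)`` where the covariance is the
    biased (1/N) covariance matrix of the points.  Collinear sets are fine;
    fully coincident sets are not.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need at least two 3D points")
    centred = pts - pts.mean(axis=0)
    if not np.any(np.abs(centred) > 1e-12):
        raise ValueError("all points coincident; direction undefined")
    cov = centred.T @ centred / len(pts)
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, np.argmax(eigvals)]
    # sign convention: point upward; for horizontal lines, first non-zero
    # component positive
    if abs(v[2]) > 1e-12:
        if v[2] < 0:
            v = -v
    else:
        nz = np.nonzero(np.abs(v) > 1e-12)[0][0]
        if v[nz] < 0:
            v = -v
    return v / np.linalg.norm(v), cov


def angle_between(v: np.ndarray, w: np.ndarray) -> float:
    """Angle in degrees between two vectors, in [0, 180]."""
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0 or nw == 0:
        raise ValueError("zero-length vector")
    c = float(np.clip(np.dot(v, w) / (nv * nw), -1.0, 1.0))
    return math.degrees(math.acos(c))


@dataclass
class TrunkTrace:
    """One growing (or finished) trunk: skeleton indices and direction state."""

    tree_id: int
    trunk_indices: list[int]
    main_direction: np.ndarray = field(default_factory=lambda: UP.copy())
    covariance: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    branch_index: int | None = None
    terminated: bool = False
    truncated: bool = False     # ran out of candidates (data gap / chain end)
    degenerate: bool = False    # never grew beyond the seed
    ambiguous_seed: bool = False

    @property
    def frontier(self) -> int:
        return self.trunk_indices[-1]


def find_seed_points(skeleton: Skeleton, base_height: float = 1.0,
                     separation: float = 1.0) -> list[TrunkTrace]:
    """One seed trace per spatially separated group of trunk-base points.

    Skeleton points below ``base_height`` are linked into groups by
    horizontal proximity (< ``separation``); the lowest point of each group
    seeds a trace.  Groups whose bottom layer holds several skeleton points
    are flagged as ambiguous (possibly merged stems).
    """
    low = np.nonzero(skeleton.positions[:, 2] < base_height)[0]
    if len(low) == 0:
        raise ValueError(f"no skeleton points below {base_height} m; "
                         "cannot seed trunks")
    xy = skeleton.positions[low, :2]
    # single-linkage grouping via union-find over close pairs
    parent = list(range(len(low)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(xy)
    for i, j in tree.query_pairs(r=separation):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(len(low)):
        groups.setdefault(find(i), []).append(i)

    traces = []
    # deterministic ordering: by seed position
    for members in sorted(groups.values(),
                          key=lambda m: tuple(skeleton.positions[low[m[0]]][:2])):
        idx = low[np.asarray(members)]
        lowest = idx[np.argmin(skeleton.positions[idx, 2])]
        bottom_layer = skeleton.layer[idx].min()
        ambiguous = int(np.sum(skeleton.layer[idx] == bottom_layer)) > 1
        traces.append(TrunkTrace(tree_id=len(traces), trunk_indices=[int(lowest)],
                                 ambiguous_seed=ambiguous))
    for t in traces:
        skeleton.state[t.trunk_indices[0]] = STATE_TRUNK
        skeleton.tree_id[t.trunk_indices[0]] = t.tree_id
    return traces


def _unclassified_density(skeleton: Skeleton, tree: cKDTree, idx: int,
                          radius: float) -> int:
    neigh = tree.query_ball_point(skeleton.positions[idx], r=radius)
    return sum(1 for j in neigh
               if j != idx and skeleton.state[j] == STATE_UNCLASSIFIED)


def _refresh_direction(trace: TrunkTrace, skeleton: Skeleton,
                       candidates: np.ndarray) -> None:
    """Principal direction over trunk points plus the current candidate set."""
    idx = np.concatenate([np.asarray(trace.trunk_indices, dtype=np.int64),
                          np.asarray(candidates, dtype=np.int64)])
    pts = skeleton.positions[idx]
    if len(pts) >= 2:
        try:
            trace.main_direction, trace.covariance = principal_direction(pts)
        except ValueError:
            pass  # coincident set: keep previous direction


def grow_step(trace: TrunkTrace, skeleton: Skeleton,
              params: SegmentationParams, tree: cKDTree) -> bool:
    """Attempt one upward growth step; returns True while the trace is live."""
    if trace.terminated:
        return False
    fr = trace.frontier
    fpos = skeleton.positions[fr]
    neigh = tree.query_ball_point(fpos, r=params.trunk_search_radius)
    cand = np.array([j for j in neigh
                     if skeleton.state[j] == STATE_UNCLASSIFIED
                     and skeleton.positions[j, 2] > fpos[2] + 1e-9],
                    dtype=np.int64)
    if len(cand) == 0:
        trace.terminated = True
        trace.truncated = True
        trace.degenerate = len(trace.trunk_indices) == 1
        trace.branch_index = fr
        skeleton.state[fr] = STATE_BRANCH
        return False

    _refresh_direction(trace, skeleton, cand)
    best: tuple[float, float, float, int] | None = None
    for c in cand:
        step = skeleton.positions[c] - fpos
        ang = angle_between(step, trace.main_direction)
        if ang >= params.angle_tolerance:
            continue
        rho = _unclassified_density(skeleton, tree, int(c), params.density_radius)
        if rho >= params.trunk_density_threshold:
            continue
        # the angle test gates candidates; among passing ones the nearest
        # continues the trunk (a farther candidate over the same lateral
        # jitter always *looks* straighter, so ranking by angle would
        # leapfrog chain points and leave them to spoof the branch-density
        # stop)
        key = (float(np.linalg.norm(step)), ang, int(c))
        if best is None or key < best:
            best = key
    if best is None:
        # branch point reached: density rose and/or direction broke
        trace.terminated = True
        trace.branch_index = fr
        skeleton.state[fr] = STATE_BRANCH
        return False
    chosen = best[2]
    trace.trunk_indices.append(chosen)
    skeleton.state[chosen] = STATE_TRUNK
    skeleton.tree_id[chosen] = trace.tree_id
    return True


def grow_trunk(trace: TrunkTrace, skeleton: Skeleton,
               params: SegmentationParams | None = None,
               tree: cKDTree | None = None) -> TrunkTrace:
    """Grow a single seeded trace until its branch point (or a data gap)."""
    params = params or SegmentationParams()
    tree = tree or cKDTree(skeleton.positions)
    while grow_step(trace, skeleton, params, tree):
        pass
    return trace


def extract_trunks(skeleton: Skeleton,
                   params: SegmentationParams | None = None) -> list[TrunkTrace]:
    """Seed and grow all trunks concurrently (round-robin sweeps).

    Concurrent traces claim skeleton points first-come; sweeping all traces
    one step at a time keeps the claiming order unbiased with respect to
    seed enumeration order.
    """
    params = params or SegmentationParams()
    traces = find_seed_points(skeleton, base_height=params.seed_base_height,
                              separation=params.seed_separation)
    tree = cKDTree(skeleton.positions)
    live = list(traces)
    while live:
        live = [t for t in live if grow_step(t, skeleton, params, tree)]
    # the branch point keeps its trace's tree id
    for t in traces:
        if t.branch_index is not None:
            skeleton.tree_id[t.branch_index] = t.tree_id
            skeleton.state[t.branch_index] = STATE_BRANCH
    return traces


def branch_points(traces: list[TrunkTrace], skeleton: Skeleton) -> np.ndarray:
    """(T, 3) array of branch-point positions, one row per trace."""
    return np.vstack([skeleton.positions[t.branch_index] for t in traces])
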