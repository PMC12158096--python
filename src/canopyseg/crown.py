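"""Crown extraction by multi-feature fusion, and the full plot pipeline.

After trunk extraction every remaining skeleton point is classified by two
fused features — horizontal distance ``d`` to the nearest branch point and
local skeleton density ``ρ``:

* ``d ≤ T_HD1`` and ``ρ ≥ ρ3`` — crown **core**, assigned to the nearest
  branch point's tree;
* ``T_HD1 < d ≤ T_HD2`` and ``ρ < ρ2`` — crown **boundary**, later assigned
  to the tree of the nearest classified skeleton point;
* ``T_HD1 < d ≤ T_HD2`` and ``ρ2 ≤ ρ < ρ3`` — **disputed** (crown-overlap
  zone), resolved by growth-direction consistency;
* ``T_HD1 < d ≤ T_HD2`` and ``ρ ≥ ρ3`` — high-density **peripheral**,
  assigned to the nearest branch point's tree;
* everything else is deferred to the boundary pass.

A disputed point E is compared against each neighbouring tree: the growth
vector from that tree's nearest classified point C to E should continue the
tree's main (trunk principal) direction; among trees whose angle stays
under the dispute threshold the smallest angle wins, otherwise nearest
distance decides.  Resolved disputes become anchors for later sweeps;
decisions within one sweep are taken from the sweep-start snapshot, so
non-interacting disputes resolve order-independently.

Finally labels are back-projected: every raw vegetation point inherits its
skeleton point's tree id, and within-layer DBSCAN noise is attached to the
nearest labelled skeleton point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud, NO_LABEL
from .params import SegmentationParams, calibrate
from .skeleton import (Skeleton, build_skeleton, STATE_UNCLASSIFIED,
                       STATE_TRUNK, STATE_BRANCH, STATE_CORE, STATE_BOUNDARY,
                       STATE_DISPUTED, STATE_PERIPHERAL)
from .trunk import TrunkTrace, extract_trunks, branch_points, angle_between

# classification outcomes of the first crown pass
CORE = "core"
BOUNDARY = "boundary"
DISPUTED = "disputed"
PERIPHERAL = "peripheral"
DEFERRED = "deferred"


def classify_crown_point(position: np.ndarray, density: float,
                         branch_xy: np.ndarray,
                         params: SegmentationParams) -> tuple[str, int | None]:
    """Classify one skeleton point; returns ``(state, tree_index | None)``.

    ``branch_xy`` is the (T, 2) array of branch-point horizontal positions;
    the returned tree index refers to rows of that array.  Interval edges
    are closed at the lower branch: ``d == T_HD1`` takes the core test and
    ``d == T_HD2`` is inside the annulus.
    """
    if len(branch_xy) == 0:
        raise ValueError("no branch points")
    dxy = np.hypot(branch_xy[:, 0] - position[0],
                   (branch_xy[:, 1] - position[1]) / params.crown_aspect)
    nearest = int(np.argmin(dxy))
    d = float(dxy[nearest])
    if d <= params.t_hd1:
        if density >= params.rho3:
            return CORE, nearest
        return DEFERRED, None
    if d <= params.t_hd2:
        if density < params.rho2:
            return BOUNDARY, None
        if density < params.rho3:
            return DISPUTED, None
        return PERIPHERAL, nearest
    return DEFERRED, None


@dataclass
class DisputeContext:
    """Everything needed to arbitrate one disputed skeleton point."""

    disputed_index: int
    position: np.ndarray
    neighbor_index: dict[int, int]       # tree id -> nearest classified point
    neighbor_distance: dict[int, float]  # tree id -> distance to that point
    growth_vector: dict[int, np.ndarray]  # tree id -> unit vector C -> E
    angle: dict[int, float]              # tree id -> angle vs main direction


def build_dispute_context(skeleton: Skeleton, idx: int,
                          classified: np.ndarray, tree: cKDTree,
                          directions: dict[int, np.ndarray],
                          radius: float) -> DisputeContext:
    """Collect per-tree nearest classified neighbours around a disputed point.

    Only anchors *below* the disputed point qualify: branches ascend from
    the trunk, so a growth vector that does not rise cannot represent the
    continuation of a tree's structure.
    """
    pos = skeleton.positions[idx]
    neigh = tree.query_ball_point(pos, r=radius)
    ctx = DisputeContext(disputed_index=idx, position=pos, neighbor_index={},
                         neighbor_distance={}, growth_vector={}, angle={})
    for local_j in neigh:
        j = int(classified[local_j])
        if skeleton.positions[j, 2] >= pos[2] - 1e-3:
            continue
        tid = int(skeleton.tree_id[j])
        d = float(np.linalg.norm(skeleton.positions[j] - pos))
        if d < 1e-12:
            continue
        if tid not in ctx.neighbor_distance or d < ctx.neighbor_distance[tid]:
            ctx.neighbor_index[tid] = j
            ctx.neighbor_distance[tid] = d
            v = pos - skeleton.positions[j]  # growth vector C -> E
            ctx.growth_vector[tid] = v / np.linalg.norm(v)
    for tid, v in ctx.growth_vector.items():
        ctx.angle[tid] = angle_between(v, directions.get(tid, np.array([0, 0, 1.0])))
    return ctx


def resolve_disputed(ctx: DisputeContext, dispute_angle: float) -> int:
    """Tree id for a disputed point, or ``NO_LABEL`` if no neighbours exist.

    The directional comparison needs an actual two-sided dispute: with
    anchors from at least two trees in range, trees whose growth angle
    stays below ``dispute_angle`` compete on the smallest angle.  With a
    single-tree neighbourhood, or when no angle qualifies or angles tie,
    the nearest neighbouring classified point decides; remaining ties
    break toward the lower tree id.
    """
    if not ctx.neighbor_index:
        return NO_LABEL
    qualifying = {t: a for t, a in ctx.angle.items() if a < dispute_angle} \
        if len(ctx.neighbor_index) >= 2 else {}
    if qualifying:
        best = min(qualifying.items(),
                   key=lambda kv: (round(kv[1], 9), ctx.neighbor_distance[kv[0]], kv[0]))
        ties = [t for t, a in qualifying.items()
                if abs(a - best[1]) < 1e-9 and t != best[0]]
        if not ties:
            return best[0]
    # fallback: nearest distance, lower tree id on ties
    return min(ctx.neighbor_distance.items(),
               key=lambda kv: (round(kv[1], 9), kv[0]))[0]


def assign_boundary(position: np.ndarray, classified_positions: np.ndarray,
                    classified_tree_ids: np.ndarray,
                    tree: cKDTree | None = None) -> int:
    """Tree id of the nearest classified skeleton point (3D, lower-id ties)."""
    if len(classified_positions) == 0:
        raise ValueError("no classified skeleton points")
    tree = tree or cKDTree(classified_positions)
    k = min(8, len(classified_positions))
    dist, idx = tree.query(position, k=k)
    dist, idx = np.atleast_1d(dist), np.atleast_1d(idx)
    near = idx[dist <= dist[0] + 1e-9]
    return int(classified_tree_ids[near].min())


def extract_crowns(skeleton: Skeleton, traces: list[TrunkTrace],
                   params: SegmentationParams,
                   max_sweeps: int = 10,
                   boundary_mode: str = "grow") -> None:
    """Run the crown passes in order: core, disputes, boundary (in place).

    ``boundary_mode``: "grow" attaches boundary points in waves of
    increasing reach (labels follow the crown structure outward); "nearest"
    assigns every boundary point in one pass against the initially
    classified set.
    """
    if not traces:
        raise ValueError("no trunk traces / branch points")
    bp = branch_points(traces, skeleton)
    bp_xy = bp[:, :2]
    trace_ids = np.array([t.tree_id for t in traces])
    directions = {t.tree_id: t.main_direction for t in traces}

    # -- pass 1: distance/density classification -------------------------
    unclassified = np.nonzero(skeleton.state == STATE_UNCLASSIFIED)[0]
    state_of = {CORE: STATE_CORE, BOUNDARY: STATE_BOUNDARY,
                DISPUTED: STATE_DISPUTED, PERIPHERAL: STATE_PERIPHERAL,
                DEFERRED: STATE_BOUNDARY}
    if len(unclassified):
        dxy = np.hypot(
            skeleton.positions[unclassified, 0][:, None] - bp_xy[None, :, 0],
            (skeleton.positions[unclassified, 1][:, None] - bp_xy[None, :, 1])
            / params.crown_aspect)
        nearest = np.argmin(dxy, axis=1)
        dmin = dxy[np.arange(len(unclassified)), nearest]
        rho = skeleton.density[unclassified]
        in_annulus = (dmin > params.t_hd1) & (dmin <= params.t_hd2)
        is_core = (dmin <= params.t_hd1) & (rho >= params.rho3)
        is_boundary = in_annulus & (rho < params.rho2)
        is_disputed = in_annulus & (rho >= params.rho2) & (rho < params.rho3)
        is_peripheral = in_annulus & (rho >= params.rho3)
        if len(traces) == 1:
            # disputes are crown-overlap arbitration; with a single tree
            # there is nothing to dispute
            is_boundary |= is_disputed
            is_disputed[:] = False
        for mask, name in ((is_core, CORE), (is_boundary, BOUNDARY),
                           (is_disputed, DISPUTED), (is_peripheral, PERIPHERAL)):
            skeleton.state[unclassified[mask]] = state_of[name]
        assign_now = is_core | is_peripheral
        skeleton.tree_id[unclassified[assign_now]] = \
            trace_ids[nearest[assign_now]]
        leftover = ~(is_core | is_boundary | is_disputed | is_peripheral)
        skeleton.state[unclassified[leftover]] = STATE_BOUNDARY

    # -- pass 2: iterative dispute resolution ----------------------------
    # distance-ordered: a disputed point is only arbitrated once a
    # classified anchor lies within the current reach, so points near
    # settled structure resolve first and their labels anchor points
    # farther out — a one-sided early decision (only the competing tree in
    # range while the own tree's structure is still unlabelled) is avoided
    reach_schedule = [params.density_radius, params.dispute_search_radius,
                      1.5 * params.dispute_search_radius,
                      2.0 * params.dispute_search_radius,
                      3.0 * params.dispute_search_radius]
    for reach in reach_schedule:
        for _ in range(max_sweeps):
            open_disputes = np.nonzero((skeleton.state == STATE_DISPUTED)
                                       & (skeleton.tree_id == NO_LABEL))[0]
            if len(open_disputes) == 0:
                break
            classified = np.nonzero(skeleton.tree_id != NO_LABEL)[0]
            ctree = cKDTree(skeleton.positions[classified])
            decisions: list[tuple[int, int]] = []
            for idx in open_disputes:
                ctx = build_dispute_context(
                    skeleton, int(idx), classified, ctree, directions,
                    max(reach, params.dispute_search_radius))
                if (not ctx.neighbor_distance
                        or min(ctx.neighbor_distance.values()) > reach):
                    continue
                tid = resolve_disputed(ctx, params.dispute_angle)
                if tid != NO_LABEL:
                    decisions.append((int(idx), tid))
            if not decisions:
                break
            for idx, tid in decisions:
                skeleton.tree_id[idx] = tid
    # disputes still without neighbours fall back to global nearest distance
    # in the boundary pass below

    # -- pass 3: boundary attachment by nearest-classified region growth --
    # waves of increasing reach: each wave assigns the boundary points whose
    # nearest classified skeleton point lies within the wave radius, then
    # newly assigned points anchor the next wave, so labels grow outward
    # along the actual crown structure instead of jumping across gaps
    if (skeleton.tree_id == NO_LABEL).all():
        raise ValueError("nothing classified before boundary pass")
    if boundary_mode not in ("grow", "nearest"):
        raise ValueError(f"unknown boundary_mode {boundary_mode!r}")
    wave = params.dispute_search_radius
    while True:
        open_pts = np.nonzero(skeleton.tree_id == NO_LABEL)[0]
        if len(open_pts) == 0:
            break
        classified = np.nonzero(skeleton.tree_id != NO_LABEL)[0]
        ctree = cKDTree(skeleton.positions[classified])
        ctids = skeleton.tree_id[classified]
        if boundary_mode == "nearest":
            inside = open_pts
        else:
            dist, _ = ctree.query(skeleton.positions[open_pts])
            inside = open_pts[dist <= wave]
            if len(inside) == 0:
                # no boundary point within reach of the classified set: widen
                wave *= 2.0
                continue
            wave = params.dispute_search_radius
        decisions = [assign_boundary(skeleton.positions[idx],
                                     skeleton.positions[classified], ctids,
                                     tree=ctree)
                     for idx in inside]
        skeleton.tree_id[inside] = decisions


def backproject_labels(skeleton: Skeleton, cloud: PointCloud) -> np.ndarray:
    """Per-raw-point tree labels from skeleton membership.

    Vegetation points inherit the tree id of the skeleton point whose member
    list contains them; DBSCAN-noise vegetation points take the nearest
    labelled skeleton point's id (in (x, y, normalized-height) space).
    Points outside the skeletonized vegetation (e.g. ground) stay -1.
    """
    if len(skeleton) and (skeleton.tree_id == NO_LABEL).any():
        n_bad = int((skeleton.tree_id == NO_LABEL).sum())
        raise ValueError(f"{n_bad} skeleton points still unlabelled")
    labels = np.full(len(cloud), NO_LABEL, dtype=np.int64)
    for tid, members in zip(skeleton.tree_id, skeleton.members):
        labels[members] = tid
    if len(skeleton.noise_indices) and len(skeleton):
        tree = cKDTree(skeleton.positions)
        h = cloud.height if cloud.height is not None else cloud.z
        q = np.column_stack([cloud.xyz[skeleton.noise_indices, :2],
                             h[skeleton.noise_indices]])
        _, nn = tree.query(q)
        labels[skeleton.noise_indices] = skeleton.tree_id[nn]
    return labels


@dataclass
class TreeInstance:
    """One segmented tree with its skeleton, branch point and raw points."""

    tree_id: int
    branch_point: np.ndarray
    branch_height: float
    trunk_skeleton: np.ndarray          # skeleton indices, ascending height
    crown_skeleton: np.ndarray
    point_indices: np.ndarray           # raw-point indices into the cloud
    truncated: bool = False
    degenerate: bool = False
    ambiguous_seed: bool = False

    @property
    def n_points(self) -> int:
        return len(self.point_indices)


@dataclass
class SegmentationResult:
    """Full output of :func:`segment_plot`."""

    instances: list[TreeInstance]
    labels: np.ndarray                  # per-raw-point tree id (-1 = none)
    skeleton: Skeleton
    traces: list[TrunkTrace] = field(default_factory=list)

    def manifest(self) -> list[dict]:
        return [{"tree_id": int(t.tree_id),
                 "branch_point": [round(float(v), 4) for v in t.branch_point],
                 "branch_height": round(float(t.branch_height), 4),
                 "n_trunk_skeleton": int(len(t.trunk_skeleton)),
                 "n_crown_skeleton": int(len(t.crown_skeleton)),
                 "n_points": int(t.n_points),
                 "truncated": bool(t.truncated),
                 "degenerate": bool(t.degenerate)}
                for t in self.instances]


def segment_plot(cloud: PointCloud,
                 params: SegmentationParams | None = None,
                 calibration_radii: tuple[float, float] | None = None
                 ) -> SegmentationResult:
    """Run the full pipeline on a normalized cloud.

    Stages: skeletonization → concurrent trunk growth to branch points →
    crown classification (core / disputed / boundary) → label
    back-projection.  The cloud must carry normalized heights.

    When ``calibration_radii`` gives the stand's (min, max) crown radius,
    the distance and density thresholds are re-derived per stand after
    trunk extraction (the published per-plot values were set the same way).
    """
    params = params or SegmentationParams()
    skeleton = build_skeleton(cloud, params)
    if len(skeleton) == 0:
        return SegmentationResult(instances=[],
                                  labels=np.full(len(cloud), NO_LABEL,
                                                 dtype=np.int64),
                                  skeleton=skeleton)
    traces = extract_trunks(skeleton, params)
    if calibration_radii is not None:
        rmin, rmax = calibration_radii
        bp = branch_points(traces, skeleton)
        dxy = np.hypot(
            skeleton.positions[:, 0][:, None] - bp[None, :, 0],
            (skeleton.positions[:, 1][:, None] - bp[None, :, 1])
            / params.crown_aspect).min(axis=1)
        annulus = ((skeleton.positions[:, 2] > bp[:, 2].min())
                   & (dxy > rmin) & (dxy <= rmax))
        if not annulus.any():
            annulus = skeleton.positions[:, 2] > bp[:, 2].min()
        params = calibrate(rmin, rmax, skeleton.density[annulus], base=params,
                           dispute_angle=params.dispute_angle,
                           crown_aspect=params.crown_aspect)
    extract_crowns(skeleton, traces, params)
    labels = backproject_labels(skeleton, cloud)

    instances = []
    for t in traces:
        mine = np.nonzero(skeleton.tree_id == t.tree_id)[0]
        trunk_idx = np.asarray(t.trunk_indices, dtype=np.int64)
        crown_idx = np.setdiff1d(mine, trunk_idx, assume_unique=False)
        bp = skeleton.positions[t.branch_index]
        instances.append(TreeInstance(
            tree_id=t.tree_id, branch_point=bp, branch_height=float(bp[2]),
            trunk_skeleton=trunk_idx, crown_skeleton=crown_idx,
            point_indices=np.nonzero(labels == t.tree_id)[0],
            truncated=t.truncated, degenerate=t.degenerate,
            ambiguous_seed=t.ambiguous_seed))
    return SegmentationResult(instances=instances, labels=labels,
                              skeleton=skeleton, traces=traces)
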