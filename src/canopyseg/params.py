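"""Segmentation parameters, published per-plot presets, and calibration.

Every threshold of the bottom-up segmentation method lives in
:class:`SegmentationParams`.  The named presets ``plotA``/``plotB``/``plotC``
carry the values reported for low/medium/high canopy-closure rubber
plantation stands; ``calibrate`` implements the stand-level rule those values
came from (distance thresholds from the crown-radius range, density
thresholds from the observed skeleton-point density distribution), so the
method can be re-tuned to any new stand the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np


@dataclass(frozen=True)
class SegmentationParams:
    """All thresholds of the segmentation pipeline (metres, degrees, counts).

    Attributes
    ----------
    layer_thickness
        Vertical slice thickness ΔHL used for skeletonization (m).
    dbscan_eps, dbscan_min_pts
        Within-layer DBSCAN neighbourhood radius (m, in xy) and core size.
    trunk_density_threshold
        ρ1 — trunk growth stops where the count of unclassified skeleton
        neighbours reaches this value (branch-point signature).
    angle_tolerance
        θth — max angle (deg) between a trunk candidate step and the trunk's
        principal direction.
    density_radius
        Radius (m) of the skeleton-point neighbourhood used for all local
        density counts.
    t_hd1, t_hd2
        Horizontal distance thresholds from branch points delimiting the
        crown core (≤ t_hd1) and the core/boundary annulus (t_hd1, t_hd2];
        chosen as the stand's min and max crown radius.
    rho2, rho3
        Crown density thresholds: in the annulus, ρ < rho2 → boundary,
        rho2 ≤ ρ < rho3 → disputed, ρ ≥ rho3 → high-density peripheral;
        within t_hd1, ρ ≥ rho3 → core.
    dispute_angle
        Max angle (deg) between a disputed point's growth vector and a
        candidate tree's main direction for directional assignment.
    trunk_search_radius
        Upward search radius (m) for trunk growth; bridges one missing layer
        without jumping to a neighbouring row.
    crown_aspect
        Mean north–south / east–west crown radius ratio of the stand.  The
        horizontal distances to branch points are measured in the elliptic
        metric ``sqrt(dx² + (dy/aspect)²)`` so the distance bands follow the
        stand's crown shape; 1.0 (the default) is the plain isotropic
        distance.
    dispute_search_radius
        Neighbour search radius (m) for disputed-point resolution.
    seed_base_height
        Height (m) below which lowest-layer skeleton points are considered
        trunk-base seed candidates.
    seed_separation
        Minimum horizontal separation (m) between distinct trunk seeds;
        closer seed groups are merged.
    """

    layer_thickness: float = 0.2
    dbscan_eps: float = 0.15
    dbscan_min_pts: int = 5
    trunk_density_threshold: int = 3
    angle_tolerance: float = 20.0
    density_radius: float = 0.4
    t_hd1: float = 1.5
    t_hd2: float = 5.0
    rho2: int = 4
    rho3: int = 11
    dispute_angle: float = 60.0
    trunk_search_radius: float = 0.6
    dispute_search_radius: float = 0.8
    seed_base_height: float = 1.0
    seed_separation: float = 1.0
    crown_aspect: float = 1.0

    def __post_init__(self) -> None:
        if not self.layer_thickness > 0:
            raise ValueError("layer_thickness must be > 0")
        if not 0 < self.t_hd1 < self.t_hd2:
            raise ValueError("require 0 < t_hd1 < t_hd2")
        if not self.rho2 < self.rho3:
            raise ValueError("require rho2 < rho3")
        if not 0 < self.angle_tolerance < 90:
            raise ValueError("angle_tolerance must be in (0, 90) degrees")
        if self.density_radius <= 0 or self.trunk_search_radius <= 0:
            raise ValueError("radii must be positive")

    def with_(self, **updates) -> "SegmentationParams":
        return replace(self, **updates)

    def to_dict(self) -> dict:
        return asdict(self)


#: Published per-stand presets (low / medium / high canopy closure).
PRESETS: dict[str, SegmentationParams] = {
    "plotA": SegmentationParams(trunk_density_threshold=3, t_hd1=1.5, t_hd2=5.0,
                                rho2=4, rho3=11, dispute_angle=60.0),
    "plotB": SegmentationParams(trunk_density_threshold=3, t_hd1=1.5, t_hd2=3.0,
                                rho2=5, rho3=15, dispute_angle=60.0),
    "plotC": SegmentationParams(trunk_density_threshold=3, t_hd1=1.2, t_hd2=3.0,
                                rho2=7, rho3=17, dispute_angle=50.0),
}


def get_preset(name: str) -> SegmentationParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def calibrate(crown_radius_min: float,
              crown_radius_max: float,
              crown_densities: np.ndarray,
              base: SegmentationParams | None = None,
              dispute_angle: float | None = None,
              crown_aspect: float | None = None) -> SegmentationParams:
    """Derive stand-specific thresholds the way the published presets were set.

    ``t_hd1``/``t_hd2`` approximate the stand's minimum and maximum crown
    radius.  ``rho3`` is the median local density of skeleton points in the
    core/boundary annulus (``t_hd1 < d ≤ t_hd2`` from the nearest branch
    point, above branch height), never below 2: typical in-crown clusters
    then classify as core or high-density peripheral while the sparse
    crown fringe flows through the boundary region growth and the
    directional dispute rule.  ``rho2`` is 40% of ``rho3`` (matching the
    ~0.33–0.41 ratio of the published presets), always at least one below.

    Parameters
    ----------
    crown_radius_min, crown_radius_max
        Stand crown-radius range (m).
    crown_densities
        Local densities of skeleton points in the annulus (between
        ``crown_radius_min`` and ``crown_radius_max`` horizontally from the
        nearest branch point, above branch height).
    dispute_angle
        Optional override of the directional threshold (the published values
        are 60° for low/medium closure and 50° for high closure).
    """
    base = base or SegmentationParams()
    crown_densities = np.asarray(crown_densities)
    if crown_densities.size == 0:
        raise ValueError("calibration requires at least one annulus density sample")
    rho3 = max(2, int(round(float(np.median(crown_densities)))))
    rho2 = max(1, int(round(0.4 * rho3)))
    if rho2 >= rho3:
        rho2 = rho3 - 1
    kw = dict(t_hd1=float(crown_radius_min), t_hd2=float(crown_radius_max),
              rho2=rho2, rho3=rho3)
    if dispute_angle is not None:
        kw["dispute_angle"] = float(dispute_angle)
    if crown_aspect is not None:
        kw["crown_aspect"] = float(crown_aspect)
    return base.with_(**kw)
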