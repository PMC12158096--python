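"""Accuracy assessment: tree matching, detection scores, crown morphology.

Tree-level matching follows the point-percentage criterion: each reference
tree is paired with the detected tree sharing the most points, and the
point-count ratio detected/reference decides the category — within
[95%, 105%] the tree is correctly segmented (TP); a reference tree whose
points were absorbed into another tree's detection is under-segmentation
(FN); a detection that is no reference tree's best match is
over-segmentation (FP).  Detection quality is summarised by recall
R = TP/(TP+FN), precision P = TP/(TP+FP) and their harmonic mean F.

Crown morphology: crown width is the mean of the east–west and north–south
horizontal extents; the canopy projection area is the area of the concave
(alpha-shape) polygon of the crown's horizontal projection.  Agreement
between detected and reference morphology is scored with R², RMSE and
NRMSE (= RMSE / mean reference value, in percent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError


# -- tree-level matching ---------------------------------------------------

@dataclass
class EvalCounts:
    """Tree-level matching outcome for one plot."""

    ground_truth_total: int
    tp: int
    fn: int
    fp: int
    ratios: dict[int, float] = field(default_factory=dict)  # truth id -> ratio
    matched_pred: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.ground_truth_total) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fn > self.ground_truth_total:
            raise ValueError("TP + FN cannot exceed the reference tree count")


RATIO_BAND = (0.95, 1.05)


def match_trees(pred_labels: np.ndarray, truth_labels: np.ndarray) -> EvalCounts:
    """Point-percentage matching of detected trees against reference trees.

    Labels are aligned per-point arrays; negative values mean "no tree".
    Each reference tree is matched to the detection with the largest point
    overlap.  When several reference trees share the same best detection,
    the largest overlap keeps it and the others count as under-segmented
    (FN).  Detections that are nobody's best match count as over-segmented
    (FP).  A uniquely matched reference tree is TP iff the detected/reference
    point-count ratio lies within [95%, 105%].
    """
    pred = np.asarray(pred_labels)
    truth = np.asarray(truth_labels)
    if pred.shape != truth.shape:
        raise ValueError("label arrays must be aligned")
    both = (pred >= 0) & (truth >= 0)
    if not both.any():
        raise ValueError("labelings share no labelled points")

    truth_ids, truth_counts = np.unique(truth[truth >= 0], return_counts=True)
    pred_ids, pred_counts = np.unique(pred[pred >= 0], return_counts=True)
    n_truth_of = dict(zip(truth_ids.tolist(), truth_counts.tolist()))
    n_pred_of = dict(zip(pred_ids.tolist(), pred_counts.tolist()))

    overlap: dict[tuple[int, int], int] = {}
    pairs, counts = np.unique(np.column_stack([truth[both], pred[both]]),
                              axis=0, return_counts=True)
    for (t, p), c in zip(pairs, counts):
        overlap[(int(t), int(p))] = int(c)

    best_pred: dict[int, int] = {}
    best_overlap: dict[int, int] = {}
    for t in truth_ids.tolist():
        cands = [(c, -p) for (tt, p), c in overlap.items() if tt == t]
        if not cands:
            continue
        c, negp = max(cands)
        best_pred[t] = -negp
        best_overlap[t] = c

    # competition for detections: largest overlap keeps the match
    claimed: dict[int, int] = {}
    for t in sorted(best_pred, key=lambda t: (-best_overlap[t], t)):
        p = best_pred[t]
        if p not in claimed:
            claimed[p] = t

    ratios = {t: n_pred_of[p] / n_truth_of[t] for t, p in best_pred.items()}
    tp = 0
    losers: list[int] = []          # reference trees absorbed elsewhere
    over_band: list[int] = []       # unique matches with ratio > 105%
    under_band: list[int] = []      # unique matches with ratio < 95%
    for t in truth_ids.tolist():
        if t not in best_pred or claimed.get(best_pred[t]) != t:
            losers.append(t)
        elif ratios[t] > RATIO_BAND[1]:
            over_band.append(t)
        elif ratios[t] < RATIO_BAND[0]:
            under_band.append(t)
        else:
            tp += 1

    # FN: absorbed trees, plus >105% detections whose surplus is NOT already
    # accounted for by an absorbed tree sharing the same detection (a merge
    # is one omission error, mirroring a split being one commission error)
    loser_preds = {best_pred[t] for t in losers if t in best_pred}
    fn = len(losers) + sum(1 for t in over_band
                           if best_pred[t] not in loser_preds)

    # FP: spurious detections, plus <95% trees whose lost points did not
    # form one of those spurious detections
    unmatched = [p for p in pred_ids.tolist() if p not in claimed]
    explained: set[int] = set()
    for p in unmatched:
        cands = [(c, -t) for (t, pp), c in overlap.items() if pp == p]
        if cands:
            t = -max(cands)[1]
            if t in under_band:
                explained.add(t)
    fp = len(unmatched) + sum(1 for t in under_band if t not in explained)
    return EvalCounts(ground_truth_total=len(truth_ids), tp=tp, fn=fn, fp=fp,
                      ratios=ratios, matched_pred=best_pred)


@dataclass
class DetectionMetrics:
    """Recall, precision and harmonic mean (full precision; NaN = undefined)."""

    r: float
    p: float
    f: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {k: (float("nan") if math.isnan(v) else round(v, ndigits))
                for k, v in (("R", self.r), ("P", self.p), ("F", self.f))}


def detection_metrics(counts: EvalCounts) -> DetectionMetrics:
    """R = TP/(TP+FN), P = TP/(TP+FP), F = 2RP/(R+P); NaN where undefined."""
    tp, fn, fp = counts.tp, counts.fn, counts.fp
    r = tp / (tp + fn) if tp + fn > 0 else float("nan")
    p = tp / (tp + fp) if tp + fp > 0 else float("nan")
    if math.isnan(r) or math.isnan(p) or r + p == 0:
        f = float("nan")
    else:
        f = 2 * r * p / (r + p)
    return DetectionMetrics(r=r, p=p, f=f)


def detection_report(per_plot: dict[str, EvalCounts]) -> pd.DataFrame:
    """Per-plot metrics table (counts plus R/P/F rounded to 2 decimals)."""
    rows = []
    for name, counts in per_plot.items():
        m = detection_metrics(counts).rounded()
        rows.append({"plot": name, "ground_truth": counts.ground_truth_total,
                     "TP": counts.tp, "FN": counts.fn, "FP": counts.fp, **m})
    return pd.DataFrame(rows)


# -- crown morphology ------------------------------------------------------

def crown_width(points: np.ndarray) -> float:
    """Mean of the east–west and north–south extents of crown points (m)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty crown")
    ext_x = float(pts[:, 0].max() - pts[:, 0].min())
    ext_y = float(pts[:, 1].max() - pts[:, 1].min())
    return 0.5 * (ext_x + ext_y)


def _circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    cross = np.abs((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                   - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))
    area2 = cross  # twice the triangle area
    with np.errstate(divide="ignore"):
        return np.where(area2 > 1e-14, la * lb * lc / (2 * area2), np.inf)


def _triangle_areas(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    return 0.5 * np.abs((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                        - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))


def _alpha_complex_stats(simplices: np.ndarray, keep: np.ndarray,
                         n_points: int) -> tuple[int, int, float]:
    """(components, holes, point coverage) of the kept triangle set."""
    kept = simplices[keep]
    if len(kept) == 0:
        return 0, 0, 0.0
    # connected components over triangles sharing an edge
    edges = np.sort(np.concatenate([kept[:, [0, 1]], kept[:, [1, 2]],
                                    kept[:, [0, 2]]]), axis=1)
    tri_idx = np.tile(np.arange(len(kept)), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges, tri_idx = edges[order], tri_idx[order]
    same = (np.diff(edges[:, 0]) == 0) & (np.diff(edges[:, 1]) == 0)
    a = tri_idx[:-1][same]
    b = tri_idx[1:][same]
    graph = coo_matrix((np.ones(len(a)), (a, b)), shape=(len(kept), len(kept)))
    n_comp, _ = connected_components(graph, directed=False)
    # Euler characteristic V - E + F = components - holes for a planar patch
    n_vertices = len(np.unique(kept))
    n_edges = len(np.unique(edges, axis=0))
    euler = n_vertices - n_edges + len(kept)
    holes = max(0, n_comp - euler)
    coverage = n_vertices / n_points
    return n_comp, holes, coverage


def projection_area(points: np.ndarray, alpha: float | None = None,
                    coverage: float = 0.99,
                    max_points: int | None = 5000) -> float:
    """Area (m²) of the concave hull of the points' horizontal projection.

    The hull is the classic Delaunay alpha shape: triangles whose
    circumradius is at most ``alpha`` (metres).  ``alpha=inf`` keeps every
    triangle — the convex hull.  With ``alpha=None`` the smallest alpha is
    chosen for which the kept triangles form a single polygon containing at
    least ``coverage`` of the points.  Dense clouds are deterministically
    strided down to ``max_points`` before triangulating (``None`` disables).
    """
    pts = np.asarray(points, dtype=float)[:, :2]
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    if max_points is not None and len(pts) > max_points:
        stride = int(np.ceil(len(pts) / max_points))
        pts = pts[::stride]
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) point set") from exc
    if len(tri.simplices) == 0:
        raise ValueError("degenerate (collinear) point set")
    radii = _circumradii(pts, tri.simplices)
    areas = _triangle_areas(pts, tri.simplices)
    if alpha is not None:
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        return float(areas[radii <= alpha].sum())

    # auto alpha: smallest circumradius threshold whose alpha complex is a
    # single hole-free polygon containing >= coverage of the points.
    # Hole-freeness is not monotone in alpha, so scan candidate quantile
    # levels in ascending order instead of bisecting.
    finite = np.unique(radii[np.isfinite(radii)])
    if len(finite) == 0:
        raise ValueError("degenerate triangulation")
    levels = np.unique(np.quantile(finite, np.linspace(0.0, 1.0, 200)))
    for a in levels:
        n_comp, holes, cov = _alpha_complex_stats(tri.simplices, radii <= a,
                                                  len(pts))
        if n_comp == 1 and holes == 0 and cov >= coverage:
            return float(areas[radii <= a].sum())
    # no candidate qualified (isolated duplicates etc.): convex hull
    return float(areas.sum())


# -- regression diagnostics ------------------------------------------------

@dataclass
class RegressionMetrics:
    r2: float
    rmse: float
    nrmse: float  # percent of the mean measured value


def regression_metrics(estimated: np.ndarray,
                       measured: np.ndarray) -> RegressionMetrics:
    """R², RMSE and NRMSE of estimates against measured reference values.

    R² uses the standard total sum of squares about the measured mean;
    NRMSE is RMSE divided by the measured mean, in percent.  A constant
    measured vector makes R² undefined (NaN).
    """
    est = np.asarray(estimated, dtype=float)
    mea = np.asarray(measured, dtype=float)
    if est.shape != mea.shape or est.ndim != 1 or len(est) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    resid = mea - est
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((mea - mea.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    nrmse = rmse / float(mea.mean()) * 100.0 if mea.mean() != 0 else float("nan")
    return RegressionMetrics(r2=r2, rmse=rmse, nrmse=nrmse)
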