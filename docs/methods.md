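# Methods

## The segmentation model

`canopyseg` implements a bottom-up, multi-feature individual tree
segmentation for row-planted, even-aged stands scanned at high density
(order 10³ returns/m²). Its core assumptions are:

- **Stems are near-vertical and spatially separated at ground level.**
  Trunk bases are the one place where trees never overlap, so seeds are
  found there rather than at canopy maxima.
- **Trunks are directionally coherent, crowns are not.** Along the stem,
  consecutive layer centroids continue the principal direction of the
  trace; at the trunk/canopy transition (the *branch point*) the local
  density of unclassified skeleton points rises and directional coherence
  breaks. Both signals together terminate trunk growth (angle tolerance
  θth = 20°, density threshold ρ1 = 3 within a 0.4 m neighbourhood).
- **Crown interiors are dense, crown fringes sparse.** Local skeleton
  density within 0.4 m separates the crown core (assigned geometrically to
  the nearest branch point) from the sparse fringe (attached by
  region growth) and the intermediate overlap zone (arbitrated
  directionally).
- **Branches ascend.** The disputed-point rule compares the *growth
  vector* — from a candidate tree's nearest classified skeleton point
  *below* the disputed point, up to it — with that tree's main direction.
  Only anchors below the point qualify, since a non-rising vector cannot
  represent branch growth. The directional comparison requires anchors
  from at least two trees (a genuine two-sided dispute); otherwise the
  nearest-distance principle decides.

## Pipeline and parameters

| parameter | default | meaning |
|---|---|---|
| `layer_thickness` | 0.2 m | slicing interval ΔHL |
| `dbscan_eps` / `dbscan_min_pts` | 0.15 m / 5 | within-layer (xy) clustering |
| `trunk_density_threshold` (ρ1) | 3 | branch-point density signature |
| `angle_tolerance` (θth) | 20° | trunk-step direction gate |
| `density_radius` | 0.4 m | all local skeleton-density counts |
| `t_hd1` / `t_hd2` | stand min / max crown radius | core zone / annulus bounds |
| `rho2` / `rho3` | stand-calibrated | boundary / disputed / peripheral bands |
| `dispute_angle` | 60° (50° high closure) | growth-angle threshold |
| `trunk_search_radius` | 0.6 m | bridges one missing layer, never a row |
| `dispute_search_radius` | 0.8 m | disputed-point anchor search |
| `crown_aspect` | 1.0 | NS/EW metric ratio (elliptic distances) |

Choices made where the design was genuinely open:

- **Within-layer clustering is planar (xy).** A 0.2 m slab makes z nearly
  constant; planar clustering keeps the eps semantics stable.
- **`dbscan_eps` = 0.15 m.** One 0.2 m slab of a stem ring (diameter
  ~0.3 m, densely sampled) must stay a single cluster, while the canopy
  must fragment at the twig-tuft scale; at eps = 0.3 m an entire crown
  becomes one cluster per layer and the density feature degenerates.
- **Trunk candidate ranking is distance-first.** The angle and density
  tests gate candidates; among passing candidates the nearest continues
  the trunk. Ranking by angle instead systematically leapfrogs chain
  points: over the same lateral jitter a two-layer step always *looks*
  straighter, and the skipped points later satisfy the ρ1 stop mid-trunk.
- **Stand calibration** (`params.calibrate`, `segment_plot(...,
  calibration_radii=...)`): t_hd1/t_hd2 are the stand's minimum and
  maximum crown radius; ρ3 is the median local density of skeleton points
  in the annulus above branch height (floor 2) and ρ2 is 40% of ρ3. The
  shipped `plotA/plotB/plotC` presets carry the published values for three
  real stands verbatim; new stands should be calibrated, not copied.
- **Elliptic distance metric.** In stands whose crowns elongate across the
  inter-row gap, horizontal distances to branch points are measured as
  sqrt(dx² + (dy/aspect)²) with the stand's mean NS/EW radius ratio; at
  aspect 1 this is the plain isotropic distance.
- **Dispute resolution is distance-ordered and snapshot-applied.** Points
  with a classified anchor within the current reach resolve first and
  anchor the next wave; decisions within a sweep are taken from the
  sweep-start state, so non-interacting disputes are order-independent.
- **Boundary attachment grows in waves** (reach 0.8 m, doubling only when
  stuck) so labels follow the crown structure outward instead of jumping
  gaps; a single-pass nearest-classified variant is available
  (`extract_crowns(..., boundary_mode="nearest")`).
- **DBSCAN noise points are re-attached** to the nearest labelled skeleton
  point at back-projection, so the final labelling covers every
  vegetation return.

## Evaluation

Tree matching follows the point-percentage criterion: each reference tree
is paired with the detection sharing most points; a unique in-band match
(ratio in [95%, 105%]) is TP. Under-segmentation (absorbed trees, and
detections above 105% not explained by an absorbed partner) counts FN;
over-segmentation (spurious detections, and trees below 95% not explained
by a spurious detection) counts FP — a merge is one omission error exactly
as a split is one commission error, and the counting is symmetric under
exchanging the two labelings.

Crown width is the mean of east–west and north–south extents; the canopy
projection area is a Delaunay alpha-shape (circumradius threshold in
metres; infinite alpha gives the convex hull). The default auto-alpha
picks the smallest threshold whose complex is a single hole-free polygon
containing ≥ 99% of the points. For *clumpy* leaf-off canopies that rule
is too tight — it traces individual twig clusters — so benchmark areas use
a fixed alpha of 0.6 m: projection holes larger than that are treated as
real crown gaps. Benchmark extents use 1%-quantile-trimmed, clustered
points only (a drip-line style measurement robust to stray returns), and
morphology agreement is reported as the R² of the fitted
detected-vs-reference line (the statistic a calibration scatter plot
shows) together with raw RMSE/NRMSE.

## The synthetic plantation

The generator emulates leaf-off plantation stands as seen by a low-flying
UAV scanner:

- **Layout.** Rectangular grids (defaults: 5 rows x 6 columns; 3 m tree
  spacing; 7 m row spacing at low closure, 4 m at medium/high) with ±15 cm
  stem jitter; trees ~13 m tall with the trunk/canopy transition near
  5.5 m; trunk lean up to 3°.
- **Trunks** are densely sampled cylinder surfaces (no slab of the stem
  ring may fragment under the default clustering).
- **Crowns** are ellipsoids filled by an arched scaffold: limbs leave the
  crotch at 38–58° elevation and steepen outward, inner ascenders keep the
  interior wooded, and no wood sits in a narrow cone directly above the
  branch point (a pruned crotch funnel — near-vertical wood there would be
  indistinguishable from a continuing trunk for *any* direction-based
  rule). Returns concentrate in truncated-Gaussian twig tufts (σ ≈ 4–5 cm,
  ~0.35 m minimum spacing) dotted along branches and scattered alongside
  them, denser toward the crown interior and sparser at the fringe —
  producing the core/fringe skeleton-density contrast the classification
  presumes. Bare-branch wood contributes only sparse line returns.
- **Crown interaction.** Crowns elongate across the wider inter-row gap
  (aspect 1.1–1.4) and interlock only in a thin shell: a crown point more
  than 0.25 m beyond the (elliptic) midline toward a neighbour is removed,
  reflecting symmetric competition in an even-aged monoculture. Closure
  presets target ~41.5% / ~68.9% / ~89.3% canopy closure by scaling crown
  radii; the achieved closure is measured (grid-cell cover, 0.5 m cells)
  and reported, never forced.
- **Ground and noise.** Ground returns cover the plot on a smooth
  multi-sinusoid surface (5 cm roughness); 0.5% of returns are displaced
  uniformly within a 2 m-inflated bounding box as outliers.
- **Sampling densities** are 1000 / 1400 / 1600 returns/m² (crown-projected)
  for the three presets — ~0.4–0.8 M returns per 30-tree stand, the same
  order as real high-density UAV acquisitions while keeping a full
  three-stand evaluation within minutes on one CPU.

What the generator does *not* model: beam divergence, occlusion and
range-dependent return loss, intensity, multi-return waveforms, understory
vegetation, leaf phenology, wind-blurred geometry. Passing the synthetic
benchmarks therefore demonstrates that the algorithm recovers trees whose
structure satisfies the model's assumptions (separated stem bases,
ascending branches, dense cores / sparse interlocking fringes) — it does
not certify performance on stands with heavy understory, deep crown
interpenetration or severe occlusion, where the reference segmentation
itself becomes ambiguous.

## Numerical details and degenerate inputs

- Identical `PlotSpec` and seed give bit-identical clouds; the entire
  pipeline is deterministic, so repeated runs produce byte-identical
  label files.
- Heights in [−0.05 m, 0) after DEM subtraction are clamped to zero (DEM
  interpolation jitter); anything lower is rejected as a ground-filter
  error. The pipeline wrapper drops residual below-DEM outliers instead.
- Ties: equidistant boundary anchors break toward the lower tree id;
  equal dispute angles fall back to nearest distance; trunk candidates
  tie-break on angle after distance.
- Degenerate trunks are flagged, not dropped: `truncated` (no upward
  candidate within reach — a data gap) and `degenerate` (never grew beyond
  the seed).
- A stand with a single tree has no disputed class: disputes are
  crown-overlap arbitration and require at least two trees.

## Known limitations

- The point-percentage criterion is strict (±5% of a tree's returns); in
  deeply interlocking canopies part of the interlock shell is assigned to
  the neighbour by any position-based rule, which bounds achievable F at
  very high closure.
- The dispute rule's discrimination weakens when competing trees' main
  directions are both near-vertical and the canopy has no directional
  structure; it then degrades gracefully to nearest-distance assignment.
- The grid-cover canopy-closure measure depends on cell size (0.5 m
  default); porous leaf-off canopies read lower at finer cells.
- LAS/LAZ IO is not included; clouds move through headered CSV and
  whitespace XYZ text.
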