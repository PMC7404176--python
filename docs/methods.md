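# Methods

## Scope and data model

`trijunct` quantifies tricellular tight-junction (tTJ) maturity in confluent
epithelial monolayers from three fluorescence channels: a junctional channel
(ZO-1-like thin boundary lines), a tricellular-marker channel
(tricellulin-like, punctate at vertices when mature), and a nuclear channel.
All coordinates are 0-based `(row, col)` with pixel centers at integers.
The central objects are the `JunctionGraph` (vertices = candidate tTJ nodes,
edges = bicellular junction pixel paths), `CellRecord` (region, polygon,
shape descriptors) and `TLRecord` (per-vertex localization score).

## Projection and contrast adjustment

Monolayers are not flat, so z-stacks are reduced with a guided block
projection: for every `block_size` (default 20 px) block, the slice with the
largest **summed** junctional intensity is chosen (sum ≡ mean at fixed block
size and robust to single hot pixels); the target channel is composed from
those same slices. Ties go to the lower slice index; the block grid is
anchored at (0, 0) and trailing partial blocks are processed as-is; a
single-slice stack passes through unchanged. The per-block chosen-slice map is
kept as provenance.

Because the tricellular marker does not enter nuclei, the mean tricellular
intensity inside the nuclear mask (Otsu threshold, hole filling, small-object
removal) estimates background noise. With `SNR = max_intensity / (2·noise)`,
the adjusted image is `clip(I − noise, 0, ∞) / SNR` — non-negative and
strictly monotone above the noise level. If the estimated noise is zero the
division is skipped with a warning and only the subtraction applies.

## Junction-graph extraction

- **Binarization**: local adaptive threshold (pixel > local mean + sensitivity
  × global SD, 51-px window) because junctional brightness varies across
  fields; global Otsu available. Morphological closing (radius 1) bridges
  1-px gaps; specks below `min_object_area` (default 64 px²) are dropped.
- **Thinning**: topology-preserving skeletonization to 8-connected 1-px
  lines; idempotent and Euler-number preserving.
- **Vertex detection**: a skeleton pixel with ≥ 3 skeleton neighbors in its
  8-neighborhood is a branch-point pixel; 8-connected clusters merge into one
  vertex at the cluster centroid snapped to the nearest cluster pixel.
  Four-fold vertices are retained as nodal points with their degree recorded.
- **Edge tracing**: skeleton paths between clusters, ordered pixel walks;
  spurs with a free end shorter than `min_branch_len` (default 10 px) are
  pruned to a fixpoint, degree-2 vertices are dissolved by concatenating
  their edges (paths bridged to stay 8-connected), and branches touching the
  image frame are kept but flagged `border`. After pruning the interior
  subdivision satisfies `V − E + C = 1` (C counted independently as
  complement components not touching the frame).
- **Vertex relocation**: the tricellular image is smoothed (σ = 1 px) and the
  brightest pixel within `search_radius` (default 5 px) of each vertex is
  accepted as a point source if it exceeds the vertex's own bicellular line
  level by ≥ `min_prominence` (default 25%). The line level is the brightest
  of the per-incident-edge median smoothed intensities just outside the
  search disk; using the brightest edge prevents the mere convergence of
  lines at a vertex (which raises the local smoothed intensity by ~15–20%)
  from counting as a puncta. Vertices without an accepted source keep their
  skeleton coordinates and are flagged `unrelocated`; no vertex moves farther
  than `search_radius`. The relocation margin implies a sensitivity floor:
  enrichment below roughly 1.3× the line brightness is not treated as a
  point source — such vertices are still scored, at their skeleton position.

Manual correction is replayed from declarative JSON edit scripts
(`add_auxiliary_point`, `move_vertex`, `delete_vertex`, `merge_vertices`,
`split_cell`); deleting a vertex joins its two remaining edges when exactly
two remain and drops dangling edges otherwise. Every applied command is
audit-logged.

## Cell geometry

Cells are 4-connected components of the skeleton complement; components
touching the frame are flagged `border` and excluded from monolayer
summaries. Polygons order the incident (relocated) vertices by angle around
the region centroid, including auxiliary edit-script points; self-intersecting
orderings flag the cell `non_polygonal` and fall back to pixel-region
measures.

- `q_a = p_a / √A_a` — exact Euclidean perimeter/area on polygons. For pixel
  regions the perimeter uses a subpixel marching-squares contour simplified
  by Douglas–Peucker (1-px tolerance); the classic weighted boundary-step
  count (1 straight, √2 diagonal) is available via
  `region_perimeter(..., method="weighted")` but biases diagonal edges by a
  few percent, which is why the contour estimator is the default.
- `AR` — major/minor axis ratio of the second-moment ellipse (collinear
  regions give ∞ with a `degenerate` flag); a minimum-area bounding-box
  variant is available.
- `σ` — interior cells per mm², with border-cell pixels excluded from the
  area denominator so the density reflects interior packing.

## The localization score T_L

Per vertex, the **tricellular mask** is a disk of radius `r_tri` (default
4 px) at the relocated coordinates intersected with a `w_bi`-dilation of the
junction network; pixels claimed by several disks go to the nearest vertex.
The **bicellular mask** is the vertex's incident edge paths dilated by `w_bi`
(default 2 px), intersected with the binarized junctional foreground, minus
every tricellular disk. With `I_tri`, `I_bi` the mean adjusted intensities,

    T_L = I_tri / (I_tri + I_bi)

The normalized form is used because a raw ratio `I_tri / I_bi` is unbounded
while the score must live in [0, 1]: the normalized form is 0.5 for a uniform
marker, tends to 1 under pure vertex enrichment and to 0 under exclusion, and
is invariant under any positive rescaling of the image. A
`tl_form="raw-clipped"` option (`min(I_tri/I_bi, 1)`) exists for sensitivity
analysis. Vertices with an empty mask are flagged `unscorable` and reported
as missing, never dropped from counts. Per-cell scores are unweighted means
over the cell's scored incident vertices; vertex-level and cell-level
aggregations are reported separately and are not interchangeable.

Group analyses: wound-front rows are breadth-first adjacency distance from a
user-identified leader cell (leader = row 1, immediate followers = row 2), so
adjacent cells always differ by ≤ 1 row; row profiles report per-row means
with SEM (missing for single-cell rows) and an interior reference over cells
≥ 15 rows behind the leader. Cell-cycle triplets call a vertex
label-homogeneous only when *all* incident cells share the label (all four
for a degree-4 vertex). Distributions are compared with the two-sample
two-sided Kolmogorov–Smirnov test (exact p when `n_a·n_b ≤ 10⁴`, asymptotic
otherwise; ranks are scale-invariant so normalization does not change D), and
condition values may be normalized by a control group's mean.

## Synthetic epithelium generator

The generator is the test bed: a centroidal-relaxed random Voronoi
tessellation (2 Lloyd iterations by default; 0 keeps elongated,
unjammed-looking cells) clipped exactly to the field by point mirroring.
Boundary lines are drawn at `boundary_width` (default 3 px) and intensity
`boundary_intensity` (200); a 2% cytoplasmic background ensures every
projection block carries guide signal. Vertices closer than the rendering
resolution (max(3 px, boundary width)) are merged into a single four-fold
nodal point, because two such vertices are indistinguishable in the rendered
image.

Vertex enrichment is **multiplicative**: boundary pixels near a vertex are
scaled by `1 + (ρ − 1)·g` with `g` a unit-peak Gaussian (σ = 2 px), so the
puncta center renders at exactly `ρ × boundary_intensity` while lines away
from vertices stay at `boundary_intensity` — this makes the bicellular-line /
puncta-center intensity ratio equal `1/ρ` and covers depletion (ρ < 1) as
well as enrichment. `ρ = 0` is the special "no punctae" case: the tricellular
channel renders identical to the junctional channel. Nuclei are uniform disks
at cell centroids. Noise is additive Gaussian (clipped at 0) — chosen over
Poisson for simplicity and exact seed-reproducibility; rendering is bitwise
deterministic for a fixed seed.

`per_vertex_expected_TL` is computed by scoring the *rendered noiseless*
tricellular image with exactly the scorer's masks on a graph built from the
true geometry — an exact oracle that inherits every discretization effect of
the rendering rather than an analytic formula.

Z-stacks assign each block an in-focus slice from a user profile;
out-of-focus slices are per-block Gaussian-blurred (σ = 2·|Δz|) and
attenuated (0.7^|Δz|) copies. Blur is applied per block (reflect boundary) so
no light leaks across blocks and the attenuation strictly orders block sums —
otherwise empty blocks would gain blurred light from bright neighbors and
the in-focus slice would not be identifiable. The wound-front variant leaves
a free strip at the top of the field, flags the front cell nearest the
midline as the leader, assigns ground-truth rows by adjacency distance, and
gives each vertex the enrichment of its youngest (lowest-row) incident cell.

### What the generator does and does not emulate

It reproduces polygonal cell geometry, thin boundary lines, vertex punctae of
controllable contrast, nuclear blobs, defocus variation and additive noise.
It does **not** model curved or ruffled junctions, intensity variation along
a single junction, a microscope PSF, Poisson photon statistics, or 3D cell
shape. Passing tests therefore demonstrate the correctness of the topology
extraction, the score arithmetic and the group statistics under realistic
geometry and noise — not robustness to every artifact of real microscopy,
where the binarization sensitivity and mask radii may need tuning.

## Problem sizes and numerical choices

Validation runs use fields a scientist would call small-but-realistic:
25-cell/512² fields for detection fidelity (10 replicates), ~150-cell/560²
fields (≥ 200 scored interior vertices) per enrichment ratio in
{0.25, 0.5, 1, 2, 4, 8} at 5% noise, and 120-cell wound fields pooled over 8
replicates for the row gradient. Vertices within a few pixels of the image
frame are excluded from accuracy metrics: the frame closes the field of view,
so its T-points are segmentation artifacts, not tricellular junctions.

Other conventions: binarization failure and empty nuclear masks raise errors
with remediation hints; negative values after background subtraction clip to
0; KS comparisons require ≥ 2 observations per group; all randomness flows
from a single integer seed; reruns with one config are byte-identical.

## Known limitations

- Relocation only seeks intensity maxima; depleted vertices (ρ < 1) keep
  their skeleton coordinates, whose ~1 px placement error slightly biases
  their scores — visible only as a small upward shift at very strong
  depletion.
- The leader cell is user-supplied (or taken from ground truth in synthetic
  studies); there is no automatic leader detection.
- Edit-script `split_cell` inserts the dividing edge into the graph; the
  resulting cells appear after re-segmentation of the rasterized graph, not
  retroactively in an existing segmentation.
- Fucci cell-cycle phase calling from raw fluorescence, velocimetry and
  time-lapse tracking are out of scope; phase labels and velocities are
  inputs.
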