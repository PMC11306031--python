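# Methods

This note documents the models and procedures implemented in `rootqsm`,
the parameters that matter, the numerical choices made where the design was
open, and what the synthetic benchmark does and does not establish.

## Coordinate conventions

All internal coordinates are meters, right-handed, Z-up. Diameters are
reported in centimeters (the field convention for root calipering); lengths,
areas and volumes stay in m / m² / m³. Excavated root systems are scanned
collar-up; reconstruction proceeds from the collar outward, so clouds are
inverted with `z′ = (z_min + z_max) − z`, which keeps z positive and is an
involution — any rigid alternative differs only by a translation.

Supported exchange formats are ASCII and binary-little-endian PLY,
whitespace XYZ, and LAS 1.2 point format 0. PLY is written in ASCII with
double-precision vertex properties so fixtures are diffable and round-trips
hold to 1e-6 m; the bundled LAS reader/writer covers exactly the subset
above (scale 0.0001 m, offset at the floor of the min corner, preserving
mm-scale noise structure through the integer quantization).

## Preprocessing

*Statistical outlier removal*: a point survives iff its mean distance to its
`k_neighbors` (default 8) nearest neighbors is at most the cloud-wide mean
plus `std_ratio` (default 2.0) standard deviations of that statistic. These
are the common SOR defaults for TLS-density clouds. A 1e-12 m epsilon on the
cutoff keeps perfectly symmetric point patterns from losing points to float
jitter.

*CP thinning*: the cloud parameter CP is interpreted as a cubic voxel edge
length in meters (the stated sweep range 0.001–0.004 then corresponds to
1–4 mm, consistent with TLS millimeter accuracy; the interpretation is an
assumption, as the tool this knob is named after does not document its
units). Within each occupied voxel of a world-anchored grid, the single
point nearest the voxel centroid survives (ties to the lowest index).
Keeping an original point rather than the centroid means later cylinder
fits see true surface samples, not synthetic averages; the fixed grid makes
point counts monotone in CP.

## Skeletonization

The cloud becomes a symmetric k-NN graph (default k = 10) with Euclidean
edge weights; disconnected components — occlusion gaps are common in root
scans — are bridged by repeatedly inserting the globally shortest
inter-component edge. k-NN is used in place of a 3D Delaunay triangulation:
for surface-sampled clouds both give equivalent geodesics, at a fraction of
the cost.

Geodesic distances are computed with Dijkstra's algorithm. Two source
conventions are provided:

- `shortest_path_tree(graph, vertex)` — the textbook single-source tree,
  used by the oracle tests;
- `collar_shortest_path_tree(graph, cloud)` — the variant the pipeline
  uses, seeded from **every** point within 1 cm of the lowest z. From a
  single surface vertex, geodesic distance wraps around the collar (points
  on the far side of the basal ring are ~πr away, several bins for a thick
  collar), which smears the lowest bins into spiral artifacts and shreds
  the trunk base into parallel chains; multi-source seeding makes distance
  behave like arc length along the root, with the whole collar
  cross-section at distance ≈ 0.

Points are binned by `⌊dist/bin_length⌋`. The bin length is the
height-segmentation knob HS; the conventional field-scale default is 0.5,
but a useful bin must resolve individual branches, so desk-scale synthetic
roots are processed at 0.02–0.05 m (0.04 m in the shipped tests — about one
trunk radius, the scale at which one bin spans one trunk ring). Within a
bin, clusters are the connected components of the neighbor graph restricted
to the bin; any cluster whose spatial extent (exact maximum pairwise
distance, convex-hull accelerated — a bounding-box diagonal overestimates a
ring's extent and causes spurious splits) exceeds 4× the bin length is
sub-split by K-means with k = 2, 3, … until all parts are compact
(`n_init=3`, `random_state=0` for determinism). Cluster centroids become
skeleton nodes; each node's parent is the node containing the shortest-path
parents of the majority of its members (ties to the spatially nearest
candidate; rare cycles are cut and rerouted to the nearest lower-bin node).
Leaf nodes with fewer than `prune_min_points` (default 5) members are
folded into their parents.

## Cylinder model

One cylinder per skeleton edge, fitted to the member points of the edge's
endpoint nodes by damped nonlinear least squares (Levenberg–Marquardt,
`xtol = ftol = 1e-8`, ≤ 200 iterations × 5 parameters): axis point (2 dof in
the plane orthogonal to the seed direction), axis direction (2 dof as
in-plane perturbations), radius. The residual is point-to-axis distance
minus radius. At a bifurcation, the junction node's members mix several
roots and bias the fit, so junction-edge cylinders are fitted from the
child node's points alone whenever those suffice (≥ 14 points).

The standalone `fit_cylinder` returns endpoints at the extreme projections
of its points onto the fitted axis. Inside the model, cylinder endpoints
are the skeleton node positions instead, so that consecutive cylinders meet
exactly and every branch is a contiguous chain; the fit contributes radius
and RMSE. Failed fits (too few points, degeneracy, non-convergence) receive
a radius diffused from tree-adjacent successful fits and are flagged
`fitted=False`. A tapering prior caps every child radius at 1.2× its
parent's (flagged `clamped=True`) — occlusion and misregistration noise
inflate radii, and the cap bounds the damage.

Two systematic length corrections, both validated against the generator's
analytic totals: terminal cylinders are extended to the extreme
member-point projections (skeleton chains otherwise stop at the last bin
centroid, truncating every tip by ~half a bin), and each side branch's
first cylinder is extended backward along the branch centerline (estimated
from its second cylinder) to the closest approach with the parent's axis,
recovering the buried run between the parent's central axis and the
lateral's emergence from its surface. Without these, total length is biased
low by 5–8% at desk scale.

## Branching orders

Branches are rebuilt from the cylinder tree bottom-up. At each bifurcation
the *continuation* child keeps the parent's order and all other children
get order + 1. The default continuation rule is by radius — the thickest
child continues — with two robustness refinements: the radius compared is
the median over the child's first ≤ 3 unbranched cylinders (one biased fit
at the junction cannot steal the trunk), and a child whose downstream path
dies within 2.5 median cylinder lengths is never chosen when a sibling
carries real length (roots do not end at bifurcations; such twigs are
junction artifacts). The alternative longest-path rule is available as
`continuation="length"`. Leaf branches shorter than 2× the bin length are
pruned as skeletonization stubs — far below any real lateral, which spans
many bins.

## Trait extraction

Totals (length, volume `π r² L`, lateral area `2π r L` — end caps are
internal at joints and excluded, the usual QSM convention) run over all
cylinders and are exactly additive over branches. Counts apply the
coarse-root field rule to each branch's *measured* basal diameter: only
roots thicker than 0.5 cm count, and the headline `n_roots` covers orders
0–2 (taproot, first- and second-order laterals), matching how field crews
tally excavated root systems. The reported mean basal diameter averages the
counted roots.

Basal diameter (RD) is measured from the point cloud, not the cylinder fit:
the local cloud is rotated so the branch's centerline is vertical
(orientation taken from the second cylinder — the first spans the junction),
and three 1-cm slabs are sliced above the attachment, each projected to the
plane and fitted with a least-squares circle (Kåsa algebraic solve plus one
Gauss–Newton pass; exact on noiseless arcs of any coverage). RD is the mean
slab diameter in cm. Slab count, thickness, and offset are configurable.
Three safeguards handle the geometry near an attachment: points on the
parent's surface are excluded (within 1.3× parent radius + 4 mm of its
axis), the slab window starts past that exclusion zone, and each slab's
circle fit is iteratively residual-trimmed with slab diameters > 30% off
the slab median discarded. On the synthetic presets these bring worst-case
RD errors from ≈ 50–130% (parent-ring capture) to < 5%. When a measurement
is impossible (too few points), extraction falls back to 2× the fitted
basal radius.

Detection metrics need a TP/FP/FN bookkeeping: `match_roots` matches
detected to reference roots of the same order one-to-one by basal-position
distance within a tolerance, closest pairs first (Hungarian optimal
assignment behind `optimal=True`). TN is left 0 — open-world detection has
no candidate universe of non-roots — so Accuracy is reported only when TN
is supplied. Reported tables round half-up to 2 decimals (0.785 → 0.79);
full precision is kept internally. Because per-order strata have unequal
sizes, the "overall" row is reported in both aggregations (pooled counts
and per-order means).

## Synthetic root systems

The generator builds a taproot plus first- and second-order laterals as
straight chains of short (0.1 m) constant-radius cylinders whose radii
follow a linear taper `r(s) = r₀(1 − taper_rate·s)`, floored at 0.2 r₀ —
piecewise-constant taper keeps every ground-truth trait an exact finite
sum. Laterals attach at stratified heights with jittered insertion angles
and azimuths (child azimuths are redrawn until the branch does not dive
below the collar, keeping the collar the lowest structure); child basal
radius is `child_radius_ratio` × the parent radius at the attachment.

Default parameters describe the study conditions the package targets: a
mature deep-rooted tree with ≈ 2 m rooting depth, 8 cm taproot basal
diameter, coarse laterals of 1–4 cm, surface point density 2×10⁴ pts/m²
(≈ 4–5 mm spacing, a merged multi-station TLS scan), and optional radial
Gaussian noise with σ = 1 mm, the accuracy class of survey-grade
scanners. Two fixed-seed presets encode the canonical habits: `vertical`
(2 m taproot, 35° insertion) and `horizontal` (0.9 m taproot, 72°
insertion, longer laterals).

Sampling is Poisson per cylinder (λ = density × lateral area) with
per-cylinder seeded substreams, so changing one branch leaves every other
branch's points bit-identical. Noise perturbs the radius (clipped at ±6σ);
occlusion removes a contiguous angular sector per branch — a scanner
shadow, the dominant TLS failure mode — rather than random dropout.

What the generator does **not** emulate: curved and forking root paths,
bark texture and non-circular cross-sections, registration error between
stations, ground/soil returns, fine-root fuzz, and density falloff with
range. Passing the recovery tests therefore shows the pipeline is correct
and unbiased on clean tubular geometry at realistic density and noise — not
that field scans of tangled root crowns will reach the same accuracy.

## Verification summary

The shipped tests and `scripts/acceptance.py` check, among others: exact
agreement of Dijkstra distances with an all-simple-paths enumeration on 200
random small graphs; agreement of the cylinder NLLS radius with a
brute-force tilt×radius grid search; exactness of the triangle
normal/centroid primitives against cross-product/mean oracles (1e-12) and
of circle fits on noiseless arcs (rms < 1e-9); full-pipeline recovery on
both presets — exact order-0/1/2 counts, total length within 5%, volume and
area within 10%, every basal diameter within 5% at zero noise, and mean RD
error ≤ 5% with detection F1 ≥ 0.9 across 20 seeds at σ = 1 mm; bit-level
determinism of repeated runs; and monotonicity of the coarse-root threshold
filter. Problem sizes: presets of ≈ 16k–23k points, reconstructed at
HS = 0.04 m, CP = 0 (the tests probe reconstruction, not thinning; the CP
sweep has its own tests).

## Known limitations

- The reconstruction assumes one connected root system with the collar at
  the bottom; multi-tree scans must be cropped first.
- Geodesic binning cannot separate two roots that touch along their length;
  they merge into one branch with a late bifurcation (this is also the
  failure mode behind the residual order-3 artifacts on the horizontal
  preset, whose second-order laterals genuinely intersect).
- Radii below ~3× the noise σ are biased upward by the circle/cylinder
  fits' noise floor.
- HS and CP interact with scan scale; the defaults target multi-meter
  field scans and desk-scale work needs HS in centimeters.
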