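# Methods

## The growth model and its normative semantics

The radial growth model treats each colony as a front expanding at a
constant speed from a fixed seeding point, arrested locally by contact with
another colony or the arena wall. We give it a single, deterministic
semantics: **competing first-arrival propagation**. Colony *i* claims grid
cells in increasing arrival time

    T_i(x) = L_i(x) / v_i ,

where `L_i(x)` is the shortest stencil-path length from the seed cell of
*i* to *x* through cells that are empty or already claimed by *i*, and
`v_i` is the colony's rate (mm/h). Once claimed, a cell is never
relabelled; cells whose centres lie outside the arena boundary are
unclaimable; exact arrival ties go to the lowest colony label. This is
implemented as a multi-source Dijkstra sweep keyed by `(time, label)`
(numba-compiled; one pass per simulation, independent of the number of
snapshot times). Because claims are monotone in time, a snapshot at any
`t <= t_max` is obtained by masking the arrival field, and the interface
band is always re-derived from the truncated partition, never cached.

Two consequences anchor the test suite:

- **Equal rates.** Along a shortest path from the winning seed to a cell,
  every intermediate cell is also won by that seed (a strictly closer seed
  at an intermediate point would be closer at the endpoint too). The
  "through own territory" constraint is therefore inactive, and the
  partition equals the nearest-seed (Voronoi) assignment up to
  discretisation.
- **Unequal rates.** The constraint is active: a fast colony reaching
  around a slow one must detour along geodesics hugging the slow colony's
  boundary. Near the seeds the interface follows the Apollonius boundary
  `|x−c₁|/v₁ = |x−c₂|/v₂`; far from the seeds the wrap-around closes
  behind the slow colony, which ends engulfed and bounded. Both the
  straight-line (Apollonius) partition and the simulated geodesic one are
  exported, since they genuinely differ behind the slow colony and the
  appropriate reference depends on the question.

### dmin (interface band)

Real colony interfaces show a visible low-cell-density gap. After
propagation, any claimed cell within `dmin/2` (world units) of a cell
claimed by a different colony is recoded to the interface code (−1),
removing the band symmetrically from both sides. The default is
`dmin = 0` (sharp partition): the width of the real gap is a property of
the organism and medium, not of the model, so it is left to the user.

### Stencil order and metric anisotropy

Front steps use the stencil of all coprime integer offsets with max-norm
`<= r` ("order r"). The induced path metric overestimates Euclidean
distance by at most sec(γ/2) − 1 for the largest angular gap γ between
stencil rays: ~8.2% at order 1 (8-/26-connected), ~2.8% at order 2, ~1.3%
at order 3, ~0.5% at order 5 (2D). The package default is **order 2** — at
the 8-connected order 1 the anisotropy distorts a free front by more than
one cell already at radii of ~20 cells, while order 2 keeps free fronts
circular to ~1 cell up to radii of ~50 cells at roughly twice the cost of
order 1. Checks that quantify convergence to exact Euclidean growth (the
Voronoi-equivalence and circularity properties) are run at order 5, where
the residual directional error (~0.5%) is comfortably below the tolerances
being verified; this is a discretisation-accuracy knob exactly analogous
to grid resolution, which those checks also fix.

Two further discretisation conventions matter when comparing against
references. Seeds are snapped to the centre of their grid cell (half-cell
displacement at most); reference partitions are therefore built from the
*effective* (snapped) seed positions. And mathematically exact equidistance
ties — which arise systematically for symmetric arrangements, e.g. whole
tie columns in the cross preset — are resolved to the lowest label in the
reference constructions with a 1e-9 relative tolerance on squared
distances, matching the simulator's documented tie rule instead of letting
float round-off decide.

## Reference partitions

`voronoi_2d` builds each polygon as the intersection of the clip region
with the half-planes toward its seed against every other seed: O(K²)
but exact for the seed counts used here (tens), and robust for collinear
or cocircular seeds without perturbation. Disk arenas are clipped to a
≥128-segment polygon. Adjacency is detected by intersecting cell
boundaries after an epsilon buffer (independently clipped neighbours agree
only to float precision). `voronoi_label_grid` is implemented twice —
chunked brute-force argmin (the oracle; first-occurrence argmin gives the
lowest-label tie rule) and a KD-tree route whose near-ties are re-resolved
brute-force — and the two are cross-checked exactly in the tests.
`region_hulls_3d` hulls the *corners* of a region's boundary cells, so the
hull encloses whole cells: for convex regions hull volume ≥ voxel volume,
with the staircase excess (≈ half a cell over each face) shrinking with
resolution — the convexity diagnostic `hull/voxel ≤ 1.05` needs ~128 cells
across the domain for 4–5 regions.

## Similarity metrics

Jaccard is |A∩B|/|A∪B| (undefined and rejected when both masks are empty).
The Chamfer distance extracts boundary cells by face connectivity (a true
cell with a false 4-neighbour in 2D, 6-neighbour in 3D; array edges count
as false) and symmetrises as the mean of the two directed mean
nearest-boundary distances, scaled to mm; the directed pair is available
for asymmetric questions. Pearson is computed on the 0/1 fields and
rejected for constant masks. The multi-label report computes all three per
paired label and aggregates with **experimental mask areas** as weights
("union" areas are a flag away); pooled four-category agreement counts
(both / experiment-only / simulation-only / neither) are computed over the
evaluation region, which can be restricted to a crop. Labels present but
unpaired, or paired labels empty on exactly one side, are errors rather
than silent omissions.

## Seeding and rate inference

`TimelapseGrowthModel` assumes frames are co-registered label grids with
consistent labels (a greedy maximal-overlap `match_labels` is provided for
stacks labelled per frame). The centre estimate is the centroid of the
colony's largest connected component in the earliest frame where it
appears — for data starting near inoculation this is within a cell of the
seed; from a single post-collision frame it is systematically biased away
from interfaces, which the model reports rather than hides. The rate
estimate regresses the colony's mean *uncollided* boundary radius on
acquisition time: boundary cells within `exclusion_cells + dmin_cells`
(default 2) of foreign territory, the interface band, or the arena wall
are dropped as collided. Fitted slopes are divided by a **discrete-front
calibration factor**: the mean claimed radius of a simulated unit-rate
colony grows as `c·t` with `c ≈ 0.984` (order-2 stencil, 2D) because of
the same metric anisotropy described above; the factor is measured once
per (dimension, stencil order) by running a single-colony simulation and
applying the identical measurement procedure, and cached. Without it,
rates are biased ~1.5% low and re-simulations of noise-free fits lag their
own input. Frame times must be supplied explicitly and strictly
increasing.

## Synthetic data

The generator emulates what segmented scanner/confocal masks of these
experiments look like, with ground truth retained. Arrangement presets
cover the study layouts: an equilateral triangle (40 mm spacing in the
worked example), square/cross/hexagon grids (3 cm order), a compact
hexagon (5.5 mm), points on an annulus, uniform random "disordered"
seedings with a minimum separation of max(spacing, 4 cells), and cube
vertices in 3D. Pseudo-experimental rendering perturbs each colony's
boundary along its signed-distance normal by a smooth periodic angular
noise (random Fourier series with Gaussian angular spectrum; std =
`boundary_sigma` mm, correlation length `boundary_corr` degrees, default
30°, mode 0 excluded so the mean radius is preserved; a Gaussian random
field is used in 3D), erodes an interface gap of `gap_width`, and flips a
`speckle_rate` fraction of cells. Defaults are zero noise; the degradation
and recovery studies use `boundary_sigma` = 0.25–1 mm on 0.2 mm grids,
i.e. 1–5 cells of boundary roughness, bracketing what hand segmentation of
soft-agar scans plausibly leaves. All randomness flows through explicit
seeds (frames get independent child seeds); identical seeds are
bit-identical and each manifest records its seed.

What the generator does **not** emulate: dendritic swarming fringes,
intensity/optics effects beyond a smoothed two-channel rendering,
registration error between frames, and segmentation failure modes that are
not local boundary noise (merged colonies, holes). Passing recovery tests
on this generator therefore shows the inference is correct for radially
grown, locally-noisy masks — not that it is robust to arbitrary real
segmentation artefacts.

## Problem sizes and numerical choices

The verification runs use 500×500 cells (0.18 mm on a 45 mm-radius dish)
for the 2D equivalence checks, 128³ for the 3D consistency checks, 20
seeded replicates per noise level for the Monte-Carlo properties, and a
cube spacing of 21.375 mm chosen so both seed planes coincide exactly with
cell-centre planes of the 48 mm box. Tolerances follow the discretisation:
1.5 cells (Hausdorff) for front circularity, per-label Jaccard ≥ 0.99 for
partition equivalence, 2 cells for centre recovery, 5% for rate ratios.
Degenerate inputs are rejected loudly (seeds outside the arena or sharing
a cell, nonpositive rates or times, empty masks, constant masks for
Pearson, shuffled frame orders); degenerate 3D hull regions are flagged,
not fatal.

## Known limitations

- The stencil metric is anisotropic at any finite order; boundaries
  inherit a directional error of order the stencil bound times the seed
  distance. Raise `stencil_order` (cost grows ~quadratically in 2D,
  ~cubically in 3D with the order) when boundary placement matters.
- Interface carving is Euclidean post-processing; it does not model the
  dynamics inside the gap.
- The geodesic wrap-around partition for unequal rates is this package's
  reading of contact-inhibited growth; the straight-line weighted partition
  is provided alongside because published "weighted Voronoi" comparisons do
  not always distinguish the two.
- Rate inference assumes constant rates; decelerating fronts (nutrient
  depletion) will show as curvature in the radius–time regression and a
  large RMS residual, which is reported per colony.
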