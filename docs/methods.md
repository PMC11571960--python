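# Methods

`microvasc` quantifies 3D microvascular networks from volumetric
fluorescence images: light-sheet stacks of brain vasculature labeled either
intravascularly (FITC-albumin hydrogel; perfused lumens appear as solid
tubes) or by immunostaining of vessel walls (iDISCO-style; vessels appear
hollow). This note records the models, estimators, defaults, and the
numerical choices behind them, and what the bundled phantom generator does
and does not establish.

## Coordinate and unit conventions

Axis order is (z, y, x) everywhere. Voxel spacing is physical, in µm per
voxel, and defaults to (2, 1, 1): light-sheet stacks are acquired at 2 µm
axial steps, and the lateral pixel size of ≈1 µm follows from a 6.5 µm
camera pixel at 6.4× magnification. The lateral value is an inference, not
a stated acquisition parameter, and is configurable everywhere. The
physical position of voxel (i, j, k) is its center, (index + 0.5)·spacing.
ROI crops are half-open physical boxes [offset, offset + extent); the
default analysis ROI is 305 × 305 × 600 µm (x, y, z), i.e. 305 × 305 × 300
voxels at default spacing.

## Phantom generator

The generator produces a `PhantomTruth`: a set of constant-radius tubes
(straight segments, optionally circular arcs) with analytically known
length, volume, junctions, tortuosity and diameters, so that every
downstream stage can be validated against closed-form ground truth.

**Network growth.** Networks grow by seeding isolated root tubes and
bifurcating at existing tips (probability `branching_prob`, default 0.7).
Every bifurcation creates exactly one degree-3 junction; degree-2
continuations are never created, so each tube is one branch of the true
graph. Candidate tubes are rejection-sampled subject to: containment in the
ROI with a margin of the maximum radius + 2 µm; a minimum centerline
clearance of r₁ + r₂ + 4 µm between tubes (trimmed near shared junctions),
which keeps tube *surfaces* at least 4 µm apart so that segmentation never
merges distinct tubes; child directions within 20–50° of the parent and at
least 40° of each other; and a minimum junction separation of 12 µm. An
attempt budget of 400 × n_segments bounds the rejection sampling; a network
that does not fit raises "phantom too dense" rather than looping forever.
Default radii are 2.0–3.2 µm (diameters 4–6.4 µm, spanning the intermediate
and large caliber classes and resolvable at 2 µm axial spacing) and default
tube lengths 25–80 µm, the scale of cortical capillary branches.

**Rasterization.** Straight tubes are rendered as *flat-capped* finite
cylinders — foreground where the radial distance to the axis is ≤ r and the
axial coordinate lies within the segment — so the rendered volume matches
the analytic π r² L with no spherical-cap excess. The hollow (wall-labeled)
mode takes the (−wall, 0] band of the same inside/outside field, which is a
closed shell: lateral wall plus end disks. Two consequences are used by the
tests: the hollow render is a voxelwise subset of the solid render, and
tube lumens are sealed cavities that interior filling can recover. Arcs use
the capsule field (centerline distance − r) with the centerline sampled at
min(spacing)/2; the polyline chord error is ≤ step²/8R and negligible.
Tubes thinner than one voxel trigger a warning and a guaranteed
one-voxel-wide centerline rasterization.

**Blur and noise.** PSF blur is an isotropic-in-µm Gaussian applied after
rasterization (sigma divided per-axis by the spacing). The camera model is
Poisson shot noise (default 100 photons at the foreground intensity, SNR ≈
10) plus Gaussian read noise (default σ = 2 intensity units) and a baseline
offset (default 5) — the standard sCMOS model, chosen to keep SNR
controllable with two interpretable parameters. With noise disabled the
render is exactly binary {0, peak}.

**Analytic truth metrics.** Length, branch count, junction count,
tortuosity (arc length / chord; π/2 for a semicircle) and diameters are
exact. Vessel volume sums π r² L and subtracts, per junction of degree k,
(k − 1)·(2/3)π·min(rᵢ)³ for tube overlap inside the junction ball. This
correction is approximate (the true intersection of cylinders at arbitrary
angles has no convenient closed form); for clearance-constrained networks
the residual error is well under the 5–10% tolerances used in volume tests.

**Spots.** Spheres with exactly known surface distances to each caliber
class. Distances are computed against the analytic tubes (capsule surface
distance); a spot requested at distance d from a class is accepted only if
no other tube alters the derived label. Labels follow the proximity rule
below, with the ≤ 10 µm boundary inclusive.

## Segmentation

**Background subtraction.** The rolling-ball step is implemented as a
grayscale white tophat with a physically sized, flat *rectangular*
structuring element spanning 2 × 20 µm per axis. A true ball footprint of
that size (21 × 41 × 41 voxels, non-separable) is computationally
infeasible at full ROI size on one core; the separable window preserves the
operation's contract — constant images map to ~0, structures smaller than
the window keep their contrast — which is what the tests pin down.

**Vesselness.** Frangi tubularity over two scale sets, small {1, 2} µm and
large {3, 5} µm, bracketing the caliber classes. Hessians are built from
Gaussian derivatives with per-axis sigmas of scale/spacing (anisotropy
enters only here), converted to physical second derivatives and
scale-normalized by scale². Eigenvalues of the 3×3 symmetric Hessian are
computed with the closed-form trigonometric method, vectorized over the
volume — per-voxel LAPACK calls are two orders of magnitude slower at 28M
voxels. Frangi parameters α = β = 0.5; the structureness scale γ is half
the maximal Hessian norm per scale. A response floor treats images whose
Hessian magnitude is below 1% of the intensity maximum as structure-free,
so float32 roundoff on flat images cannot be amplified by the final
normalization. Each scale set is normalized to [0, 1] before the per-voxel
maximum is taken, putting capillaries and larger vessels on equal footing.

Two properties of this filter shaped the pipeline around it. First, on a
thin tube the *mismatched* (large) scale set responds in a wide halo, so
thresholding vesselness alone bleeds beyond the tube; `segment_volume`
therefore uses vesselness as a loose detection gate (> 0.2 by default) and
the configured intensity threshold (Otsu by default) for delineation,
intersecting the two. Second, the rim of a solid bright sphere is locally a
genuine curvilinear structure at fine scales and is *not* suppressed — only
the blob's center response is (by the Frangi blobness term). The
sphere-vs-tube test therefore compares center responses, which is what
"centerline-style response" means operationally.

**Hollow filling.** Wall-labeled segmentations pass small-object removal →
morphological closing with a physically sized ellipsoidal ball (default
radius 2 µm, above the sub-2 µm wall gaps of the hollow phantom) → 3D
interior-cavity filling: background components (6-connectivity) not
connected to the volume border become foreground. Foreground connectivity
is 26, background 6 — the complementary pair that avoids the digital
topology checkerboard paradox. The mask is padded by the structuring
element before closing so border voxels are treated correctly, and the
output is explicitly united with the input, making the operation monotone;
it is idempotent on its own output. If the closing radius is below the wall
gap size, lumens leak to the border and stay unfilled; a diagnostic second
pass at twice the radius detects this (> 15% extra volume) and warns rather
than silently under-filling.

## Skeletonization and graph

**Thinning.** The package ships its own 3D curve thinning
(`microvasc._thinning`, numba-accelerated): border-sequential deletion of
simple points over the six face directions, with candidates re-tested after
every deletion, preserving curve endpoints. Simplicity uses the
Bertrand–Malandain characterization (exactly one 26-connected foreground
component in the 26-neighborhood and one 6-connected background component
in the 18-neighborhood touching the voxel), which guarantees homotopy
preservation: loops stay loops, components stay components. This exists
because the environment's scikit-image 0.26 3D skeletonize erases entire
even-width objects (a ball or a 4-voxel-wide rod returns an *empty*
skeleton), which breaks every downstream guarantee.

**Graph extraction.** Skeleton voxels of degree ≥ 3 (26-connectivity) are
clustered; each cluster becomes one junction node at its voxel centroid
(cluster enumeration is deterministic; ties break on the lowest linear
voxel index). Degree-1 voxels are endpoints. Maximal degree-2 paths between
nodes are branches; isolated cycles get a single anchor node (lowest linear
index on the cycle) and a self-loop branch.

**Branch length.** Physical step lengths are summed along the voxel
centerline after an endpoint-pinned moving average (window 5 voxels). Raw
26-connected digital paths overestimate oblique straight lines by up to
~10%, which alone would exceed the 5% length tolerance; smoothing removes
the staircase while pinned endpoints keep length ≥ chord. Two end
corrections make lengths faithful to the tube extent: free (endpoint) ends
are extended by the local EDT radius along the local direction, because
thinning retracts the skeleton by roughly one radius from each tube end;
junction-terminated ends are connected to the junction centroid, recovering
the span of the junction cluster. Net length bias on phantom networks is
−2 to −4%.

**Tortuosity** is length/chord with the chord between the (corrected)
branch end positions. Cycle branches whose ends coincide have chord 0;
their tortuosity is undefined (NaN), excluded from averages, and they are
counted separately — the defining ratio divides by the inter-junction
distance, which is zero here.

**Branch diameter.** Default estimator (`diameter_mode="area"`): every mask
foreground voxel is assigned to its nearest skeleton voxel (exact
physical-distance query via a k-d tree) and a branch with claimed volume V
and length L gets diameter 2·√(V/(π L)). Voxel counting has no centering
error, so this is accurate to well under half a voxel across radii 1.5–5 µm
— tip-extended lengths pair with the end-cap volume those ends claim. The
simpler estimator (`"edt_mean"`, 2 × mean EDT along the path with
junction-ball trimming at the ends) is retained as a config option but is
biased low by up to ~half a voxel because the thinned path can sit off the
true axis; it cannot meet a ±0.5 µm diameter tolerance at 1 µm spacing.
The per-voxel `radius_field` (EDT minus half the smallest spacing,
estimating distance to the surface rather than to the background sample
point) remains the basis for tip extension and trimming.

**Pruning.** Endpoint-terminated branches shorter than 5 µm (default) are
removed — below the smallest caliber boundary, these are thinning
artifacts, not capillary stubs. Junction pairs connected by a branch
shorter than 8 µm are fused (position: midpoint), because thinning at a
true bifurcation of thick tubes regularly yields two junction clusters a
few µm apart; 8 µm sits safely below the 10 µm minimum junction separation
the phantom world guarantees, so fusion cannot merge distinct true
junctions there. On real data with closer junctions this default must be
lowered. Intra-junction sliver edges that fusion would turn into
self-loops are dropped. Nodes reduced to degree 2 are dissolved, merging
their branches (lengths add, diameters length-weighted, chord and
tortuosity recomputed). `prune_spurs(g, 0, 0)` is the identity.

## Metrics and stratification

Per ROI: (a) length density (Σ branch length / ROI volume, reported in both
µm/µm³ and mm/mm³), (b) branching-point density (junctions / volume),
(c) volume density (foreground fraction), (d) branch density, (e) mean
branch length, (f) mean tortuosity over branches with nonzero chord,
(g) mean diameter. The report-level mean diameter is length-weighted
(robust to branch fragmentation); the unweighted mean is emitted alongside.
Empty graphs report zero densities and *absent* (not zero) means.

Caliber classes partition (0, ∞) by mean branch diameter: small < 4 µm,
intermediate 4–5.4 µm, large > 5.4 µm. Both printed bounds belong to the
middle class — the closed middle interval is the only reading consistent
with "<4", "4–5.4" and ">5.4". Assignment is branch-level (by mean branch
diameter), matching the branch-wise stratified quantities (per-class
length density, branch density, mean branch length, mean tortuosity). Since
every branch lands in exactly one class, per-class sums equal totals to
machine precision, which the tests assert exactly.

## Spots

Detection is multi-scale Laplacian-of-Gaussian with anisotropy-aware,
physically scaled sigmas (for a solid sphere of radius r the response peaks
near σ = r/√3). The scale search extends to twice the 9.75 µm cap so
oversized aggregates are measured at their true size and then rejected,
rather than clipped into range and kept. Sigmas are clamped to at least one
voxel per axis — sub-voxel scales alias on sharp edges. The 9.75 µm
"maximum size" is interpreted as a cap on the fitted spot diameter, the
only reading that yields a concrete filter.

Assignment measures, per spot, the Euclidean distance (in µm) from the spot
center to the nearest foreground voxel center of each caliber-class mask —
center-to-surface, mirroring spot-center-based proximity tools; the label
is the class with the smallest distance among those ≤ 10 µm (inclusive),
exact ties resolved small > intermediate > large (deterministic, favoring
the rarer event), otherwise "unassociated" — the operational definition of
an aggregate not associated with a perfused microvessel. The k-d-tree
implementation computes the same metric as an exhaustive scan over all
foreground voxels; tests verify exact agreement of labels and distances.

## Pipeline and reproducibility

A `RunConfig` (YAML-loadable) drives phantom-or-file input, ROI crop,
segmentation, graph extraction, metrics and spots. All randomness flows
from the single config seed via `numpy.random.default_rng`; reruns of the
same config produce byte-identical CSVs. The manifest records the config
(and its hash), seed, package and library versions and per-stage wall
times: the original analyses hinge on configuration their publications do
not print, so this artifact always prints its own.

## What the phantom does and does not establish

The generator states a world of piecewise-constant-radius, largely straight
tubes with clearance-separated centerlines, ideal PSF blur and sCMOS-model
noise. Green tests establish that segmentation, topology, length, volume,
diameter, tortuosity and proximity measurements are mutually consistent and
accurate *in that world* at stated tolerances (junction counts exact at
≥ 10 µm separation; length density ±5%; volume density ±10%; diameters
within max(10%, half the coarsest voxel)). They do not establish
performance on real tissue: tapering and tortuous vessels, labeling
heterogeneity, vessel-touching-vessel geometry below the clearance bound,
scattering artifacts and anisotropic PSFs are all outside the stated world.
The learned (3D U-Net) segmentation used for wall-labeled data in the
original analyses is out of scope; the classical morphological route
implemented here is the label-generation procedure that analysis itself
describes, and it is fully testable.

## Known limitations

- Thinning is voxel-topological and ignores anisotropy; at (2,1,1) µm the
  skeleton is still correct topologically, but sub-voxel centering in z is
  coarser, which the area-based diameter estimator absorbs.
- The junction-fusion default (8 µm) presumes junction separations above
  10 µm; dense capillary beds need a smaller value and will then show
  split-junction overcounts near true bifurcations of thick vessels.
- Truth volume at junctions is approximate (sphere-cap overlap correction).
- Arcs are rendered as capsules (round caps), so an arc's rendered volume
  slightly exceeds π r² L at its free ends.
- `detect_spots` assumes roughly spherical, well-separated objects;
  touching aggregates merge.
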