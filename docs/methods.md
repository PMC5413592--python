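# Methods

This note records the models behind each measure, the parameter choices that
matter, what the phantoms do and do not emulate, and the numerical decisions
a user extending the package should know about.

## Fractal dimensionality of voxel structures

Both voxel estimators reduce a binary mask to a scale series (s, N(s)) and
fit `log N = -D log s + c` by unweighted ordinary least squares in natural
logs; D is reported with the slope, intercept and r² so users can judge and
prune scales. Estimates outside (0, 3] are flagged in the log but reported
as computed.

**Box counting.** N(s) is the number of occupied s×s×s boxes, anchored at
index 0 of the mask's foreground bounding box; partial boxes at the far
edges count. No multi-offset averaging is applied: grid-placement
sensitivity is a documented property of plain box counting, and the
dilation method exists precisely to remove it — averaging the grids would
blur that contrast.

**Dilation counting.** The mask is dilated on its own grid by a cubic
kernel of width s (growth beyond the grid boundary is clipped — the
`same`-size convolution convention) and N(s) = dilated voxels / s³. At
s = 1 this is the raw voxel count. Clipping makes grid-filling solids scale
exactly like box counting (a 16³ cube reads D = 3.000), and a grid-spanning
slab or line reads exactly 2 or 1. When the dilated set stays inside the
grid, the series is exactly invariant to translation of the structure —
the property box counting lacks. The kernel is a cube, not a ball; with a
ball the s = 1 identity and the cube-exactness both break.

**Scales.** Default {1, 2, 4, 8, 16} voxels. Self-similar test fractals
built on powers of 3 (the Menger sponge) override with {1, 3, 9, 27},
where the box counts form an exact geometric series and D is recovered to
machine precision. Scales must not exceed the largest grid dimension.

**Surface variant.** The one-voxel boundary shell: foreground voxels with
at least one 6-connected background neighbor, the volume border counting
as background. Note a finite-size effect worth knowing: for a shell of
side L, dyadic box counts only scale like a surface while s ≪ L (at s
comparable to L every box touches the shell and the series mimics a
solid); shell phantoms should be ≥ 64 voxels per side before the fitted D
approaches 2. Dilation on a 1-voxel shell thickens it symmetrically, so
its small-scale counts behave like a 3-voxel slab and read high; the shell
oracle checks use box counting.

**Regional FD.** Each labelled region is masked, cropped to its bounding
box with a one-voxel pad, and estimated independently. Regions under 20
voxels are flagged `unreliable` (a 3-point log fit on so few voxels is
dominated by discretization) but still reported; absent labels are skipped
with a warning. Smaller parcels trend toward lower D — they approach
simple convex solids — so regional values should be compared across
sessions or groups, not against whole-structure values.

## SPHARM fractal dimensionality (surfaces only)

A closed genus-0 mesh is mapped to the unit sphere; its x, y, z coordinate
functions are fit by least squares against a real orthonormal
spherical-harmonic basis up to the largest requested band-limit; the
surface is reconstructed at each band-limit l and its triangle area A(l)
measured. Since a band-limit l probes spatial scale ∝ 1/l and the measured
area of a fractal surface at probe scale δ grows like δ^(2−D),

    D = 2 + d log A(l) / d log l.

A smooth sphere has flat A(l), hence D = 2 exactly — the baseline the
tests pin at 2 ± 0.05. Folding adds fine-band area and raises D
monotonically. The estimate is invariant to rigid motion (checked to
0.02). Default band-limits {2, 4, 8, 16, 32}, log-spaced; (l_max+1)² must
not exceed the vertex count, and the least-squares fit must be full rank.

**Parameterization.** Radial projection about the centroid, which is
fold-free for star-shaped meshes (all phantoms here; near-star-shaped
anatomical surfaces in practice). If any spherical triangle flips,
uniform-weight Laplacian relaxation on the sphere (step 0.5, renormalized,
up to 200 iterations) is applied; unresolved folds raise an error rather
than silently distorting the expansion. This is the simplest fold-safe
scheme; it does not attempt the area-preserving parameterizations used by
dedicated SPHARM toolchains, so coefficients are comparable within a
pipeline, not across parameterization methods.

## Gyrification index

GI = surface area / enclosing-surface area, computed per closed structure
(not vertex-wise; reproducing geodesic-ROI local gyrification is out of
scope, and the reliability machinery is agnostic to which GI flavor fills
the session matrix). Two enclosing surfaces are offered:

- **convex hull** of the vertices (default; deterministic, exact via qhull);
- **morphological closing**: voxelize at 1 mm, binary-close with a ball of
  radius 15 mm (the scale used in the local-gyrification literature;
  configurable), extract the boundary by marching cubes over a mildly
  smoothed field (σ = 1.5 voxels — raw binary marching cubes inflates
  areas ~10% through voxel staircasing). The closing is computed with two
  Euclidean distance transforms; a voxelized ball structuring element at
  r = 15 would be orders of magnitude slower.

A subtlety the phantom suite exposes: for a *mildly* bumpy near-convex
surface the convex hull can have slightly **more** area than the surface
(tangent "tents" over isolated peaks add more than the shallow folds do),
so GI dips below 1. This is a property of the geometry, not a bug. The
bumpy-sphere phantom therefore defaults to a dense perturbation
(spherical-harmonic bands up to degree 32 on a subdivision-5 icosphere,
peak displacement = amplitude), where folding dominates and GI rises
strictly with amplitude: 1.000, 1.007, 1.083, 1.202 at amplitudes
0, 2, 5, 8 mm on a 50 mm sphere.

## Cortical thickness

For each white-surface vertex w: t(w) = ½ (d(w, pial) + d(p_w, white)),
where p_w is the nearest point on the pial surface and the second term is
the distance back from p_w to the white surface. Distances are exact
point-to-triangle (barycentric clamping), so the measure does not depend
on the two meshes sharing topology or vertex density; candidate triangles
are prefiltered with a k-d tree over triangle centroids (24 candidates,
sufficient when triangles are small relative to the gap — the regime of
anatomical and phantom meshes). Intersecting surfaces legitimately yield
zeros, which are counted and logged, not rejected. On concentric shells
(40/50 mm) the mean recovers the analytic 10 mm gap within 0.05 mm even
when the pial shell is re-meshed and rotated; the swap white↔pial changes
shell means by < 0.5%.

## Reliability framework

**ICC(1)** — one-way random effects, consistency of single measurements:
`(MS_B − MS_W) / (MS_B + (k−1) MS_W)` on a complete n×k matrix, CI from
F = MS_B/MS_W with quantiles at (n−1, n(k−1)) df. Negative estimates are
reported as computed (truncating at 0 would break the coverage
properties). Incomplete designs are rejected, not imputed — the estimator
assumes a complete matrix, and the multi-session designs this targets are
complete. Category bands use inclusive lower edges: ≥.75 excellent,
[.60,.75) good, [.40,.60) fair, else poor.

**Mean deviation** — per subject, the mean absolute deviation of the k
session values from that subject's own mean (the per-row spread annotated
on session dot plots). A pairwise mean-absolute-difference reading is
available behind `scheme="pairwise"` since the quantity is not uniquely
defined by its common usage.

**Mann–Whitney** — two-sided. The z statistic always comes from the
normal approximation with tie-corrected variance and continuity
correction (the form in which such comparisons are conventionally
reported). The p-value uses tie-aware exhaustive enumeration of group
assignments when C(n, n_a) ≤ 2×10⁵ — at group sizes ≤ 8 the normal
approximation can be off by up to ~0.08 — and the asymptotic form at
region scale (62 regions), where it is accurate.

**Exceedance curves** — for each x, the fraction of values ≥ x
(right-continuous), evaluated on a caller grid or the sorted sample.

## The session simulator

`simulate_sessions` draws y_ij = μ + b_i + e_ij with b ~ N(0, σ_b²),
e ~ N(0, σ_w²) — exactly the generative model under which ICC(1) is
defined, with true reliability ρ = σ_b²/(σ_b²+σ_w²). Defaults mirror a
30-subject × 10-session design at ρ = 0.8 (σ_b = 2, σ_w = 1, grand mean
2.5 — a cortical-thickness-like scale); the two study geometries exercised
throughout are 30×10 and 69×2. One explicit seed per call; no global RNG
state.

What passing tests show — and what they do not: the simulator validates
the *statistical* machinery (estimator recovery within 0.05 at 1000
seeds, 95% CI coverage calibrated to [93%, 97%]) under the model's own
assumptions of Gaussian, homoscedastic, exchangeable sessions. Real
test–retest data add scanner drift, session-order effects, segmentation
failures and heavy tails, none of which are emulated. Likewise the mesh
phantoms validate geometric correctness (analytic areas, gaps,
monotone folding response), not anatomical realism: no medial wall, no
variable cortical curvature, no segmentation noise.

A note on interval widths across designs: fewer sessions carry less
information, and at fixed n the k=2 intervals are clearly wider than k=10
(0.28 vs 0.18 at ρ=0.8, n=30). Across the two study geometries the larger
n of the 69×2 design offsets its smaller k almost exactly at ρ=0.8
(widths equal to three decimals), while at ρ=0.4 the 69×2 intervals are
distinctly wider (0.40 vs 0.29) — near the ρ→1 ceiling all intervals
compress against the upper bound.

## Numerical and interface decisions

- Voxel indices 0-based; world coordinates via the NIfTI affine; meshes in
  mm world space. Phantom voxels default to 1 mm isotropic so scales read
  in voxels (FD is scale-free; mm matter only for volume/thickness).
- Label volumes stored as float are accepted only if integral within 1e-6.
- PLY is written with double-precision vertex properties (round-trips to
  1e-6 mm); FreeSurfer binary surfaces are float32 by format definition,
  so their round-trip is exact only to ~4e-6 mm at brain coordinates. MGZ
  and FreeSurfer surfaces are optional conveniences; NIfTI and PLY/OFF are
  the native dialects.
- Session CSVs are long-format `subject, session, metric, value`; measure
  outputs add a `region` column that the reliability reader folds into the
  metric name.
- Pipeline runs are deterministic given config + seed; the resolved config
  is copied into the output directory.

## Known limitations

- Dilation counting loses its translation invariance for structures within
  one kernel-width of the grid boundary (growth clips asymmetrically);
  keep a margin of at least the largest scale when building masks.
- The spherical parameterization is not area-preserving; strongly
  non-star-shaped surfaces may fail to unfold and will raise.
- Regional thickness aggregation is an unweighted vertex mean (no
  area weighting); with strongly non-uniform meshes an area-weighted mean
  would differ.
- The closing-based GI hull depends on voxelization pitch and smoothing σ
  at the few-percent level; the convex hull is the reproducible default.
- Two-way ICC models (absolute agreement), Bland–Altman and Dice-overlap
  spatial reliability are out of scope.
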