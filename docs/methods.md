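# Methods

## The segmentation model

The cord is modeled as a generalized cylinder around a smooth centerline. The
centerline is a Catmull-Rom (piecewise cubic Hermite) spline through control
points selected as an equally distributed subset of the user's markings; the
first marking (the ponto-medullary junction analog) is the arc-length origin
z = 0. The cylindrical system (z, θ, r) uses arc length for z, the distance
to the nearest spline point for r, and an angle θ measured from a fixed
reference direction d̂₀ projected into the plane orthogonal to the local
tangent. The frame assumes the query point lies in the normal plane of its
nearest spline point and that d̂₀ is never parallel to the tangent; both are
checked, and a 30 mm capture radius bounds the region where the nearest-point
problem is trusted.

The boundary model is purely one-dimensional: along each radial ray the
gradient-magnitude profile is assumed to characterize the cord/CSF interface
well enough that rays with similar profiles (by normalized cross-correlation)
have their boundary at a similar radial index. Matching transfers the known
edge index of manually segmented template rays onto new test rays; no shape
prior beyond per-slice star-convexity (implied by rasterizing one edge
distance per angle) is imposed.

## Parameters

| parameter | default | meaning |
|---|---|---|
| initial control points | 20 | spline through the user markings |
| radials per slice | 179 | 2° increments, angles {0°, …, 356°} |
| profile length | 70 voxels | ray walk, 0.1 mm steps, deduplicated nearest voxels |
| test stations | 100 | evenly spaced in arc length over the marked extent |
| match target | 50 templates | averaged to infer the edge index |
| threshold schedule | 1.00, step 0.02 | highest level with ≥ 50 qualifying templates |
| threshold floor | 0.30 | below it: top-50 by raw NCC, flagged as fallback |
| median kernels | 5, 7, 9 | cascade over θ (circular) then z (reflect), optional |
| refined control points | 500 | per-slice centroids resampled evenly in z |
| d̂₀ | world +x | θ = 0 reference; configurable |

The counts (179, 70, 17,900 = 100×179, 20, 500) and the threshold schedule
are the method's standard operating point; they are defaults, not constants,
and every stage takes them as arguments.

NCC uses population (1/n) normalization. A constant profile has zero variance;
its similarity is defined as 0 and it can never qualify as a match. Equal NCC
values are tie-broken by database insertion order so runs are deterministic.
An NCC within 1e-6 of a schedule level counts as reaching it, so that
bit-identical profiles (similarity 1 up to float rounding) match at the 1.00
threshold.

## Design choices where the design was open

- **Segment map.** The index map sometimes written for this construction
  (i = t·(N−1), t′ = N·t−i) does not keep t′ in [0, 1); we use
  i = ⌊t·(N−1)⌋, t′ = t·(N−1) − i, the only reading consistent with a local
  parameter in [0, 1).
- **Tangent scaling.** Standard Catmull-Rom tangents (P_{i+2} − P_i)/2 are
  the default (shape-preserving, independent of N); the literal N-scaled
  variant is available via `n_scaled_tangents`. The control-point
  interpolation property holds under both.
- **θ sign.** arccos alone is unsigned; we resolve the sign with the frame
  e₂ = tangent × e₁, yielding θ ∈ [0, 2π), which the 179-angle fan requires.
  On the half-plane where arccos is single-valued the two definitions agree.
- **cyl→euclid normalization.** The perpendicular projection of d̂₀ is
  normalized before scaling by r, so euclid→cyl→euclid round-trips exactly.
- **Edge index → mm.** Matching averages edge *indices* (templates and tests
  are built by the identical voxel walk, so index space is the commensurate
  one); the mean index is converted to mm along the test ray afterward. The
  boundary for integer edge e is placed where the walk crosses from voxel e
  into voxel e+1 (half a 0.1 mm step before the next voxel's first sample) —
  the midpoint of the two voxel centers along the ray, an unbiased boundary
  estimate for uniformly distributed sub-voxel phase.
- **Smoothing order.** The median cascade operates on the per-station matched
  edges, before interpolation to the remaining axial slices: outliers are
  created by matching, so they are removed at matching resolution (kernel 9
  there spans ~9 station gaps of cord length rather than 2.7 mm of slices).
  `smooth_edge_field` itself accepts either field.
- **Rasterization plane.** Edge distances are measured in the plane
  orthogonal to the tangent but rasterized in the axial plane with angles
  about the world +x axis. At cervical-scale curvature (tangents within a few
  degrees of the slice normal) the difference is far below voxel size.
- **Templates in the axial plane.** Template rays use the axial plane (the
  manual masks are axial); test rays use the tangent-orthogonal plane. Same
  justification.
- **Fallback.** The threshold schedule alone does not define what happens
  when 50 matches never materialize; we stop at a floor of 0.30, take the top
  50 by raw NCC, and flag the cell so smoothing and inspection can treat it.

## The phantom generator

Phantoms emulate the imaging conditions the method targets: a darker cord
(intensity 60) with a piecewise-linear radius around 4–5 mm (rising toward a
cervical enlargement, then falling), a bright CSF ring (240, thickness
1.5 mm), mid-intensity surrounding tissue (120), voxels at the native
0.3906 × 0.3906 × 0.3 mm spacing, additive Gaussian noise (σ = 5 by default;
a deliberate simplification of MR noise), sinusoidal in-plane curvature
(amplitude ~1–2.5 mm), thin dark rootlet-like streaks crossing the ring at
the C3–C8 marker levels, and optional z-intervals where the ring is replaced
by tissue intensity (obliterated CSF, the documented failure mode — the
default stress case uses two 5 mm intervals, severe enough that unsmoothed
matching visibly degrades and the median cascade recovers it).

Truth is analytic: the mask is exactly the set of voxels whose center lies
within the local radius of the closed-form centerline, so metric oracles are
exact. Grids use odd in-plane voxel counts so the cord axis sits on a voxel
center; an axis on a half-voxel corner puts axis-aligned rays on a rounding
knife-edge where float noise flips nearest-voxel selection.

What the phantoms do **not** model: MR physics (k-space, bias fields, Rician
noise statistics, partial volume), motion, vertebral/disc anatomy beyond a
uniform tissue background, and pathology. Passing phantom tests therefore
demonstrates the pipeline's geometric and algorithmic correctness under the
intended contrast ordering — not clinical performance on real images.

## Problem sizes

The shipped cohort uses six phantoms on 63 × 63 × 200 grids (a ~24 mm field
of view around the cord, 59.7 mm of cord length), which yields 35,800
templates from the database subject and the full 17,900 test arrays per
segmentation. The self-consistency scenario uses a straight, noise-free,
constant-radius (4.5 mm) phantom of 120 slices: there, every test ray
reproduces a template ray exactly, all matches reach the 1.00 threshold, and
the segmentation reproduces the truth mask (Dice 1.0). Unit tests use shorter
(60–80 slice) variants of the same geometry.

## Known limitations

- Cross-sectional area inherits two small negative biases on axis-aligned
  cylinders: lattice quantization of voxel-center counting (the same
  fluctuation affects the truth mask itself) and the phase-coherent boundary
  estimate of the last-inside-voxel edge convention. On the 5 mm test
  cylinder the truth mask reads ~1.4% below π·25 and the segmentation ~2%
  below; on curved, varying-radius cords the phases decohere and the biases
  largely average out.
- The fixed-d̂₀ frame is not rotation-minimizing; θ is not continuous along
  strongly twisting curves. Irrelevant at cervical curvature, by design.
- Hausdorff distance is dominated by the first/last segmented slices when the
  segmented extent differs from the reference by even one slice.
- Matching cost is O(test arrays × templates × 70); with one database subject
  this is a few seconds of BLAS time, but the database grows linearly with
  ground-truth subjects and no pruning or z-windowing is enabled by default
  (an optional z-window restriction is deliberately out of scope).
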