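# cordseg

Semi-automatic segmentation of the spinal cord from high-resolution 3-D MR
volumes by **one-dimensional normalized template matching**, together with the
validation-metric suite used to score segmentations (Dice, mean centerline
distance, Hausdorff distance, regional cross-sectional area) and a synthetic
cord-phantom generator that provides analytic ground truth.

The package is aimed at spinal cord imaging researchers who need reproducible
cord masks, arc-length distances along the cord, and cross-sectional areas
(e.g. for atrophy quantification) from T2-weighted volumes where bright CSF
surrounds a darker cord.

## Method

A user marks the approximate cord centerline on the new image (first point at
the ponto-medullary junction, PMJ). The markings initialize a Catmull-Rom
spline **p**(t) through N = 20 control points,

    p(t) = P_{i+1} h00(t') + m_i h10(t') + P_{i+2} h01(t') + m_{i+1} h11(t'),

with Hermite basis functions h_ij, segment index i = ⌊t·(N−1)⌋, local
parameter t' = t·(N−1) − i, and ghost end points so the end tangents aim at
the adjacent control point. Arc length s(t) = ∫‖p′‖dt defines the
longitudinal coordinate z of a generalized cylindrical system (z, θ, r)
around the cord: θ is measured from a fixed reference direction d̂₀ in the
plane orthogonal to the local tangent, r is the distance from the axis.

Segmentation works on the **gradient image** (voxelwise gradient magnitude,
which peaks at the cord/CSF interface):

1. **Templates.** From a ground-truth (manually masked) subject, 179 radial
   rays per axial slice (2° increments) emanate from each slice's mask
   centroid. Each ray is walked in 0.1 mm steps, recording a gradient value
   whenever the nearest voxel changes, until 70 voxels are collected (~27 mm;
   positions beyond the image border contribute zeros). The index of the last
   in-mask voxel is the template's edge index. One subject yields tens of
   thousands of templates (the *template database*).
2. **Matching.** 17,900 *test* arrays (179 radials × 100 stations evenly
   spaced in arc length) are extracted the same way from the new image and
   compared against every template by normalized cross-correlation,
   NCC = (1/n)Σ(f−f̄)(t−t̄)/(σ_f σ_t), which is invariant to affine intensity
   changes. The matcher starts at a threshold of 100% and decrements by 200
   basis points until 50 templates qualify; the cord edge along that ray is
   the mean of the matched templates' edge indices. Below a floor of 0.30 the
   top 50 by raw NCC are used and the cell is flagged.
3. **Smoothing (optional) and interpolation.** A cascade of 1-D median
   filters (kernels 5, 7, 9; over θ with circular wrap, then along z) removes
   outlier edges caused by reduced or obliterated CSF; edges are then
   linearly interpolated to every axial slice and rasterized into a
   star-convex region about the slice center.
4. **Re-centering.** Per-slice centroids of the segmentation are resampled to
   500 control points of a refined centerline spline, from which arc
   distances and regional cross-sectional areas
   (CSA = segmented volume / region arc length) are computed between nerve
   rootlet landmarks (C3–C8).

Annotated cord MR volumes with rootlet-level ground truth are not freely
available, so the package ships a phantom generator that emulates the target
imaging conditions — bright CSF ring, darker curved cord with a cervical enlargement,
additive noise, dark rootlet-like streaks, obliterated-CSF segments — with
exact analytic truth, so the whole pipeline is testable end to end.

## Worked example

Build a template database from one phantom and segment a second, independent
phantom with it:

```python
import numpy as np
from cordseg import (generate_phantom, gradient_magnitude, build_template_db,
                     segment, SegmentOptions, dice, hausdorff,
                     mean_centerline_distance)
from cordseg.cohort import (default_cohort_configs, markings_from_truth,
                            truth_spline)

configs = default_cohort_configs(seed=0)[:2]
donor, patient = (generate_phantom(c) for c in configs)

db = build_template_db(gradient_magnitude(donor.volume), donor.truth_mask,
                       subject_id="donor")
print(f"template database: {db.n_profiles} radial profiles")

markings = markings_from_truth(patient, seed=42)   # jittered manual clicks
result = segment(patient.volume, markings, db, SegmentOptions())
print(f"matched {result.meta['n_test_arrays']} test arrays, "
      f"mean NCC threshold {result.meta['mean_final_threshold']:.3f}")

ref = truth_spline(patient)
ks = np.flatnonzero(result.mask.data.sum(axis=(0, 1)))
print(f"Dice vs truth:       {dice(result.mask, patient.truth_mask):.3f}")
print(f"centerline MD (mm):  "
      f"{mean_centerline_distance(result.refined_spline, ref, ks * 0.3):.3f}")
print(f"Hausdorff (mm):      {hausdorff(result.mask, patient.truth_mask):.2f}")
```

Output:

```
template database: 35800 radial profiles
matched 17900 test arrays, mean NCC threshold 0.952
Dice vs truth:       0.992
centerline MD (mm):  0.033
Hausdorff (mm):      1.10
```

The Dice coefficient is volumetric overlap with the analytic truth mask; the
mean distance is the per-slice gap between the refined centerline and the
true cord axis (well under one 0.39 mm voxel); the Hausdorff distance is the
worst boundary disagreement, dominated by the end slices of the segmented
extent.

The same workflow is available from the shell:

```bash
cordseg phantom --config cfg.yaml --out work/
cordseg build-templates --volume work/phantom.nii.gz \
    --mask work/phantom_mask.nii.gz --out work/db.h5
cordseg segment --volume new.nii.gz --markings markings.json \
    --db work/db.h5 --out seg.nii.gz --smooth
cordseg evaluate --pred seg.nii.gz --ref manual.nii.gz
cordseg loo-cohort --n-phantoms 6 --out report/
```

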