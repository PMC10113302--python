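# Methods

`vesselreg` registers a high-resolution vessel-tree centerline model (as
extracted from TOF-MR angiography) to the intensity ridges of a
lower-resolution scalar volume (typically the temporal maximum-intensity
projection of a PC-MRI magnitude image).  It is a hybrid model-to-image
method: the moving object is the centerline with per-point
maximum-inscribed-sphere radii, never a resampled image.

## Model and objective

Vessels appear in the fixed volume as intensity ridges: tubular loci of
locally maximal intensity.  A correctly registered centerline therefore
places every visible centerline point on a ridge crest.  The objective,
maximized over a parameterized affine transform T, is

    f(T) = a1 * m1(T) - a2 * mean_i m2_i(T) - a3 * m3(T)

with

- **m1 — scaled sum of weighted intensities.**
  `m1(T) = sum_i w(r_i) I_{k*r_i}(x_i T) / sum_i w(r_i)`,
  where `x_i` are the centerline points currently considered, `r_i` their
  radii, `I_s` the fixed volume smoothed at standard deviation `s` mm and
  trilinearly interpolated, and `w(r) = r` by default (larger vessels are
  both more visible and more reliable; `w(r) = 1` is available as an
  ablation).  The blur scale is tied to the vessel radius through
  `kappa` (default 1.0), matching the scale-space idea that a vessel of
  radius r is best localized at blur ~r.  The normalization makes m1 a
  weighted mean, so transforms cannot inflate the objective by changing
  how many points they cover.
- **m2 — ridge-centering penalty.**  At each point, the plane normal to
  the transformed tangent is sampled along `n_rays` directions (default 6)
  at `n_radii` radial offsets up to the vessel radius (default 1, i.e. at
  the radius).  The central-difference image gradient, projected onto the
  plane, is compared with the outward radial direction: the contribution
  is `(1 + cos theta)/2`, which vanishes when the gradient points inward
  toward the centerline (as it does everywhere inside a ridge) and is 1
  when it points outward.  Samples with gradient magnitude below 1e-12
  contribute 0.  The penalty is direction-only; it does not compare
  gradient magnitudes across the plane, so it centers the point within a
  ridge but cannot by itself detect a ridge of the wrong width.
- **m3 — landmark guidance.**  Mean squared distance (mm^2) between
  transformed moving guidance landmarks and their fixed counterparts.
  Landmarks placed at vessel start and end points are what anchors thin
  distal segments whose own intensity evidence is weak; without them the
  intensity term genuinely prefers contracting a thin leaf onto its
  brighter, thicker parent ridge.

Default component weights are a = (1, 0.5, 0.01 mm^-2).  Points mapped
outside the volume read intensity 0, which (with the normalization)
penalizes transforms that push the model off the image.

Per-point Gaussian blur is served from a pyramid of pre-smoothed volumes at
discrete sigma levels spaced by sqrt(2), starting at half the largest voxel
size; the level nearest `kappa * r_i` is used (below half the base level,
the raw volume).  Exact per-point blur would cost one full-volume
convolution per point; the pyramid makes the metric O(points) per
evaluation at a quantization of at most a quarter octave in scale.

## Transforms

Local transforms are anchored affines,

    M = T(t) . T(a) . R . Shear . Scale . T(-a),

acting about an anchor point `a` — for a child vessel, the branch point it
shares with its (already transformed) parent, so that zero local
translation keeps the tree connected exactly.  Euler angles are intrinsic
Z-Y-X in degrees.  The DOF ladder is 4 (isotropic scale + translation,
rotation held fixed), 6 (rigid), 7 (+ isotropic scale) and 12 (3 rotations,
3 scales, 3 upper-triangular shears, 3 translations).  A 15-parameter mode
with 6 shears exists but is experimental; 12 DOF with 3 shears already
spans all linear maps with positive determinant, so the extra shears are
redundant.

## Optimization cascade

Affine registration is dominated by rotation, so rotations are resolved
first by multi-start search rather than descent:

1. A rotation grid spans 0-30 degrees in 3-degree steps per Euler axis
   (11 values).  The default "coarse" grid varies one axis at a time
   (3*11 - 2 points); a full 11^3 product grid is available.  A mirrored
   grid covering [-30, 30] can be enabled when deformations of either sign
   are expected.
2. At every grid point the rotation is fixed and Powell's conjugate-
   direction method optimizes the 4 remaining DOF (isotropic scale,
   translation); the achieved metric is stored.
3. The grid is refined by inserting midpoints whose scores (and
   parameters) are neighbor means — interpolated, not re-optimized.
4. The `n_best` (default 3) top entries are perturbed: every parameter
   gets two perturbed copies, with magnitudes derived from voxel size v
   and brain radius R (translation v, rotation asin(v/R) — one voxel of
   displacement at brain-surface distance — scale v/R), yielding
   `1 + 2 * 7` starts per candidate for the 7-DOF stage.
5. The best 7-DOF result seeds a final 12-DOF Powell run.

Powell uses an initial direction-set step of 0.1 in each parameter's
native unit (degree, mm, unitless), an objective tolerance of 1e-6 and an
iteration cap of 1000 by default.  Scale is constrained to [0.8, 1.25] and
shear to [-0.15, 0.15]: local refinements after global initialization are
small, and the bounds keep the anisotropic stages out of two failure
modes observed without them — contraction of a weakly-constrained subtree
onto a brighter parent ridge, and aimless wandering inside the metric's
flat sub-voxel basin.  Ties in grid scores break toward smaller total
rotation, then input order.

A rigid variant of the same cascade (translation-only stage 2, 6-DOF
finish, unit scale) provides the global initialization.

### Desk-scale profile

`OptimizerConfig.desk_scale()` is the configuration used for the phantom
studies and the shipped Monte-Carlo harness: a mirrored 15-degree grid,
one kept candidate, single-iteration multi-start runs and a 6-iteration
final polish (tolerance 1e-4).  The cascade structure is identical; only
the budgets differ.  Full-scale defaults remain available for real
volumes.

## Hierarchical traversal and representation

The vessel forest (roots = inlets, leaves = outlets) is traversed
breadth-first; siblings are ordered by descending median radius.  Each
segment whose median radius reaches `factor * max(voxel size)` of the
fixed volume (factor default 1.0) is marked *represented*: visible in the
fixed volume and entitled to its own optimization.  At every represented
segment the cascade optimizes a local transform of the whole subtree
rooted there — its metric is evaluated on the represented points of that
subtree, letting distal evidence guide proximal fits — anchored at the
parent's transformed branch point.  The local transform composes onto the
accumulated matrices of the entire subtree.  Non-represented segments are
never optimized; they inherit their ancestors' accumulated transforms
exactly, which is what registers vessels too thin to be resolved in the
fixed volume.  A single forward root-to-leaf pass is performed; parents
are not revisited after their children move.

Guidance landmarks are assigned to the segment with the nearest centerline
point (in the original moving frame) and travel with that segment's
subtree during optimization.  Validation landmarks never enter the
objective; they are only measured before and after.

## Synthetic phantoms

The generator emulates the paired-acquisition setting the method is built
for, with known ground truth:

- **Tree**: recursive bifurcating tree; radii follow Murray's law
  `r_p^3 = r_c1^3 + r_c2^3` with a mildly asymmetric split (0.45-0.55 by
  default); segment length is 5x radius; polylines carry a bounded
  low-frequency sinusoidal sweep (tortuosity 0.3).  Defaults: depth 3,
  root radius 2 mm — a tree whose distal radii (~1.3 mm) remain
  represented at coarse spacing, with ~80 centerline points at 0.75 mm
  arc-length sampling.
- **Volumes**: Gaussian-profile tubes (cross-section sigma = 0.5 * radius,
  peak 1 on the centerline, maximum over segments) rasterized at
  TOF-like 0.3 mm (noise sigma 0.01) and PC-like 0.7 mm (blur 0.5 mm,
  noise sigma 0.02) spacing, matching typical 7T acquisition resolutions for the two
  modalities (~0.26-0.39 mm vs ~0.64-0.79 mm).
- **Landmarks**: guidance at inlets and outlets (vessel start/end points,
  the locations the landmark term is meant to guide), validation at
  bifurcations and leaf midpoints; the sets are disjoint.
- **Deformations**: rigid draws use a uniformly random rotation axis with
  angle U(0, 30) deg and translation U(0, 10) mm about the tree centroid;
  non-rigid draws are 4x4x4 control-point displacement fields with
  i.i.d. N(0, 5 mm) control displacements clipped at 3 sigma, trilinearly
  interpolated, with control spacing floored at 4x the jitter and
  rejection of any field whose sampled Jacobian determinant drops below
  0.05.  The 5 mm jitter makes both families start from comparable
  landmark errors.  Deformations are applied analytically to points.

What the phantoms do **not** model: MR artifacts (bias fields, flow
dephasing, ghosting), inter-modality contrast differences, segmentation
errors in the moving centerline, background vasculature and tissue, or
anatomically realistic Circle-of-Willis topology (cycles are exercised on
toy graphs in the unit tests).  Passing the Monte-Carlo studies therefore
demonstrates correct mechanics and recoverability of known deformations at
desk scale, not clinical-grade accuracy on real 7T data.

## Monte-Carlo validation

`run_mcs` repeats: sample a deformation, apply it to the moving tree and
landmark moving sides, register back to the untransformed fixed volume,
record MSE (mm^2; an RMS column in mm is included) and symmetric Hausdorff
distance (mm) of the validation landmarks before and after.  Summaries
report average/median/standard deviation per family and the fraction of
repetitions improved; failed registrations are recorded, not fatal.  Runs
are bit-reproducible given the MCSpec seed.  The shipped problem size is
20 repetitions per family on a ~45 mm field of view at 0.7 mm spacing
(about 64^3 voxels), the scale at which a full study completes on a
single desk CPU; real full-brain volumes use the same code paths with the
full-scale optimizer defaults.

## Numerical choices and degenerate inputs

- Intensity interpolation is trilinear; out-of-grid reads return the
  configured out-of-bounds intensity (default 0).
- Gradients use central differences with step half the smallest voxel.
- Endpoint tangents are one-sided differences; interior tangents central.
- Segment endpoints are matched into shared branch points at 1e-6 mm.
- Cut segments (communicating-artery analogues) keep the parent on their
  root-nearer side; the attachment at the root-farther endpoint is
  severed.  A cycle that survives the declared cuts is an error naming the
  segments involved.
- The world frame is axis-aligned LPS; NIfTI (RAS) affines are converted
  on read and write.  Volumes are float32 on disk, float64 in memory.
- Powell traces record the best value so far per iteration and are
  non-decreasing by construction; each stage starts from the previous
  stage's optimum, so stage values are monotone along the cascade.

## Known limitations

- Local affine transforms only approximate non-rigid deformation; strongly
  curved deformation within one segment is not representable.
- Sub-voxel accuracy is limited by the blurred ridge's flat basin: on a
  0.7 mm fixed volume, null-deformation drift of ~0.4-0.6 mm remains.
- The direction-only centering penalty cannot distinguish ridges of the
  wrong width; thin unguided leaves rely on the landmark term and the
  scale/shear bounds.
- One forward pass: parents are never re-registered after children move.
- Landmark-to-segment assignment is nearest-point in the moving frame and
  can mis-assign landmarks placed exactly at bifurcations of near-equal
  branches.
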