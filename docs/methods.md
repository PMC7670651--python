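# Methods

This note documents the models, the numerical choices, and the design
decisions behind `popatlas`, in the package's own words.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Spatial model and conventions

All geometry lives in world millimetres.  A volume couples a 3D scalar grid
to a 4×4 voxel-to-world affine (NIfTI sform); images are reoriented to
nibabel's closest-canonical (RAS+) axis order on load, so every downstream
operation sees one consistent axis convention.

Transforms follow the **pull (resampling) convention**: a transform maps a
point of the output (target) space to the location in the source image to
sample.  A pure translation `t` therefore moves image content by `−t`; the
test suite pins this down with a delta-spike test.  Dense warp fields store
per-voxel displacement vectors in world mm on a reference grid, so fields
defined on different grids compose consistently:
`compose(outer, inner)(x) = inner_map(x + u_outer(x))`, which equals
applying `inner` to an image first and `outer` second.  Warp inversion uses
damped fixed-point iteration `v ← −u(x + v(x))`; warp values are resampled
with cubic splines during composition because linear interpolation of a
smooth field adds measurable jitter that accumulates over a seven-stage
pipeline.

"High-order sinc" interpolation is implemented as Lanczos-windowed sinc of
radius 3, with per-axis weight renormalization so constants are reproduced
exactly.  The kernel order is a free choice; nothing downstream depends on
the exact window.

## Preprocessing

*Brain mask from labels*: union of all non-background labels, dilated 3 and
eroded 2 voxels with a 6-connected (facewise) structuring element, with
interior holes filled while dilated so they cannot reopen.

*Intensity unification*: the multiplicative bias surrogate is a per-block
median of bright-tissue intensities (bright = upper cluster of a 1D
two-means split), extended into unsampled blocks from the nearest sampled
block and Gaussian-smoothed at `sigma_mm` (default 25 mm, the approximate
spatial scale of scanner bias).  Nearest-block extension matters: filling
empty blocks with a global constant flattens the estimated field and leaves
most of the bias in place.  After dividing the field out, the white-matter
intensity mode — located by kernel density estimation over the upper
two-means cluster — is scaled to 1000, so each subject contributes equal
weight to averages.

*Axialization* fits a full 12-parameter affine to the reference, extracts
the rotation via polar decomposition (SVD), applies rotation + translation
only, and resamples onto the reference grid with windowed sinc.  Shape and
size are untouched up to interpolation; the reference grid may have any
isotropic spacing (1 mm for human-scale data, 2 mm for the desk-scale
phantoms).

## Registration

Two intensity costs are provided, both invariant to affine intensity maps:

- `lpa` — 1 − mean |Pearson r| over overlapping cubic patches of side
  `patch_mm` (50% overlap; patches with near-zero variance or fewer than 8
  in-mask voxels are excluded);
- `pcl` — 1 − Pearson r after per-image winsorization at the 2nd/98th
  percentiles (clip level is not externally prescribed; 0.02 is the
  package default).

**Affine fitting** parameterizes translation (mm), rotation (deg),
log-scales, and shears about the mask centroid, and minimizes the chosen
cost with Powell's method over a two-to-three-level resolution pyramid
(coarse 6-parameter search with a deterministic multi-start over ±12°
rotations, then 12-parameter refinement, then a full-resolution polish).
Computation is restricted to the mask bounding box.  The fit must improve
on the identity or an error is raised.

**Nonlinear registration** estimates a dense displacement field by
gradient descent:

- *force*: a demons-style update on variance-normalized images, with the
  symmetric (ESM) gradient `∇(a+b)/2` — bounded per voxel and locally
  scaled, which prevents the unbounded edge forces a raw
  correlation-gradient produces;
- *scale control*: the force is smoothed with a Gaussian of
  `patch_mm / 4` and band-limited by restriction/prolongation onto a
  control grid of spacing `patch_mm / 2` — "minimum patch size" is the
  finest scale a stage may refine;
- *regularization*: the trial total field is elastically smoothed
  (0.7 voxel) inside each line-search step, so the accepted-cost
  monotonicity guarantee applies to the regularized field;
- *acceptance*: backtracking line search; a step is accepted only if the
  configured stage cost drops by at least `rel_tol` (relative), and only if
  the deformation stays fold-free (positive Jacobian determinant at ≥ 99.5%
  of mask voxels, checked on an amortized schedule with fallback to the
  last verified field).

Both images are first blurred *as configured per stage* and then topped up
to a **matched effective resolution** (the sharper side receives the
difference in quadrature).  The stage recipes blur the source more than the
base because the base of a real pipeline is an intrinsically smooth group
mean; comparing a blurred source against a sharp base biases demons forces
at every edge, which we observed directly as systematic boundary drift.
The median source filter's window is rounded **up** to an odd voxel count
covering the stated width — at coarse voxel sizes a naively rounded window
degenerates to a no-op, and the fine stages then chase noise.

## Template driver

The stage ladder is rigid → affine → NL0…NL4 with minimum patch sizes
101/49/23/13/9 mm and pre-blurs 0/9, 1/6, 0/4, 0/2 (median), 0/2 (median)
mm.  Implementation choices that the recipe itself leaves open:

- **ICV control at every stage.**  The cohort-mean ICV (mask voxels ×
  voxel volume) is enforced after every averaging step by isotropic
  world-space rescaling about the mask centre of mass; the rescale is
  folded into every subject's running transform so the next stage sees a
  consistent geometry.  The controlled quantity is the volume of the
  fused (majority-vote) warped subject mask, and that fused mask is also
  the template's brain mask.
- **Unbiased-template recentering.**  At each nonlinear stage the
  cohort-mean increment is subtracted from every subject's increment
  (first-order centering; increments are small, so this is essentially
  exact).  Without it the cohort drifts collectively toward mutually
  convenient geometry: the SD map keeps falling while the template moves
  away from the true mean anatomy — invisible without ground truth, which
  is exactly why the synthetic study exists.
- **Stage convergence.**  Inside the driver, nonlinear steps must improve
  the stage cost by ≥ 3% (`nl_rel_tol = 0.03`); once a stage is converged
  this stops sub-noise refinements that only add independent displacement
  jitter.  Outside the driver the default is 0.2%.
- **Edge-preserving smoothing.**  Stage means are sharpened by
  Perona–Malik diffusion in flux-divergence form (global mean conserved
  exactly; conductance 30 ≈ the intensity-noise scale of an 8-subject
  mean).  The first nonlinear mean receives one fewer iteration than later
  ones (1 vs 2): it is the blurriest mean in the ladder and carries the
  least detail worth protecting, while over-smoothing it distorts the
  contrast trajectory.
- **Averaging resolution.**  Aligned subjects are resampled with windowed
  sinc for every average, and each subject is always resampled **once**
  from native space through its composed total transform — repeated linear
  resampling visibly blurs the mean.
- **CNR tracking.**  The grey/white CNR of each stage product is measured
  inside one consistent pair of tissue masks (the final stage's
  majority-vote GM and WM, boundary voxels included).  Stage-specific
  masks sharpen along with the alignment and confound the trajectory with
  a moving definition.

Parallelism is an injected order-preserving `parallel_map` (serial by
default), so the pipeline is deterministic given a seed and any conforming
executor.

## Atlas fusion

Vote counting is exact integer arithmetic; all fractions are multiples of
1/N.  Ties break to the smallest label id.  Background competes in the
vote by default — without this, cohort-edge voxels would be labelled from
single outlier subjects; `background-excluded` restores the alternative
reading.  Modal smoothing replaces each voxel by the modal label of its
(default facewise, 7-voxel) neighbourhood, keeping the current label on
ties that include it; the value set can never grow.

## Validation statistics

- The log relative volume ratio uses the natural log (the base is a free
  choice affecting only scale).  Regions absent from the MPM are reported
  as undefined, never as zero.
- The Wilcoxon signed-rank null is computed exactly for n ≤ 25 by
  convolution over doubled (mid-)ranks — equivalent to enumerating all 2^n
  sign patterns, which the test suite does literally as an oracle — and by
  a continuity- and tie-corrected normal approximation above.  Zero
  differences are dropped; the default is two-sided; the displacement
  comparison defaults to a Bonferroni factor of 15 (3 axes × 5 cohorts).
- Kendall's W is computed without tie correction (mid-ranks; the classical
  definition), with the correction available behind a flag.  The
  voxelwise ReHo map is vectorized through neighbourhood sums of temporal
  ranks and is verified voxel-by-voxel against the scalar implementation.

## The synthetic study: what it shows and what it cannot

The generator emulates: one shared anatomy (nested ellipsoids, CSF shell,
two ventricles, a folded GM ribbon in ≥ 12 parcels, WM core) with
two-scale within-tissue texture (σ = 4 mm at 10% and σ = 2 mm at 12%,
damped to 35% inside WM — white matter is far more homogeneous than cortex
on T1w); per subject a Gaussian-smoothed random displacement field (peak
amplitude 4 mm, smoothness 12 mm, positive Jacobian guaranteed by an
up-front amplitude bound plus clamping), a small rigid offset (≤ 3°,
≤ 3 mm), a smooth multiplicative bias field (0.9–1.1), and 3%-of-WM
additive noise.  The default study size is a 48³ grid of 2 mm voxels with
8 subjects; at this size the full build runs in about three minutes on one
CPU, and these sizes are reported by the acceptance script alongside every
number.

Passing tests on these phantoms show that the pipeline recovers known
geometry, controls cohort size, and improves alignment monotonically under
realistic noise, bias, and deformation magnitudes.  They cannot show
robustness to real-tissue contrast variation between scanners, pathology,
skull-strip failures, susceptibility distortion, or deformations outside
the smooth diffeomorphic family the generator produces.  Statistical
conclusions at N = 8 say nothing about power at realistic cohort sizes.

## Known limitations

- The nonlinear optimizer is a first-order method with an explicit control
  grid; it is not a numerical replica of any external registration
  program, and very large deformations (beyond the affine capture range
  plus a few control spacings) are out of scope.
- Oblique acquisitions are handled only by canonical reorientation; no
  de-obliquing is attempted.
- The subcortical-emphasis weight mask used by some axialization recipes
  is accepted as an input but no construction for it is provided.
- ReHo neighbourhoods at mask edges simply use the in-mask subset; voxels
  with fewer than two in-mask neighbours are reported as 0.
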