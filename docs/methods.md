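# Methods

`atriflow` implements a segmentation-transfer workflow for atrial 4D-flow
MRI: a high-resolution contrast-enhanced angiogram (CE-MRA) is segmented,
rigidly registered onto the phase-contrast angiogram (PC-MRA) derived from
the 4D-flow series, and the segmentation is resampled into 4D-flow
coordinates, where overlap and hemodynamics are quantified. This note
records the model choices, the numerical conventions, and what the
synthetic phantom does and does not establish.

## Coordinate and transform conventions

All geometry lives in world millimetres taken verbatim from each file's
affine (NIfTI s-form style); no axis flipping is performed, and inputs
without affines are rejected — registration between grids is meaningless
without them. Rigid transforms use intrinsic Z–Y–X Euler angles with an
explicit rotation centre; because Euler angles are gimbal-ambiguous, all
transform comparisons (tests, recovery errors) are made on rotation
matrices. Every transform in the package is a *pull-back*: it maps
fixed-image world points into moving-image world coordinates, so the
transform returned by registration feeds directly into resampling. The
rotation centre defaults to the fixed grid's centre (index `(shape−1)/2`),
a neutral choice when no anatomical centre is known.

## PC-MRA

The PC-MRA is the time average over `N` cardiac phases of magnitude ×
velocity magnitude per voxel. The implementation is a pure evaluation of
that formula: no rescaling, clipping, or masking. Velocity preprocessing
(Maxwell terms, eddy currents, anti-aliasing) is expected upstream and
non-finite inputs are rejected rather than silently masked.

## Segmentation

* **Bias correction** (PC-MRA): homomorphic — divide by a Gaussian-smoothed
  copy (scale 25 mm: far above chamber wall thickness, well below the field
  of view), floor the divisor at 10⁻⁶ of the maximum, rescale to preserve
  the global mean. The smoothing uses nearest-edge boundary handling;
  reflection would fold intensity trends back on themselves at the border
  and underestimate the bias there.
* **Region growing**: breadth-first flood fill from world-space seeds
  through face-adjacent (6-connected) voxels inside an explicit intensity
  window `[lower, upper]`. Face adjacency is conservative against leaks
  through diagonal voxel corners. The window is explicit rather than a
  tolerance around the seed mean so runs are scriptable and reproducible;
  seeds outside their window are an error, not a silent no-op.
* **Refinement**: binary median (majority vote) then morphological closing,
  both with an ellipsoidal element whose world *size* (diameter) is the
  3 mm kernel parameter — per-axis voxel radius `max(1, round(kernel/2/
  spacing))`. The diameter reading matches clinical-software semantics and
  makes the filter near-idempotent on convex segments; a 3 mm-*radius*
  ball would keep eroding convex corners (its curvature matches the
  feature curvature it creates) and changes ~5% of a 20³ cube on a second
  application.
* **Appendage separation**: a world-space plane cut; the kept side is
  restricted to the face-connected component containing the user's keep
  point, and kept/removed always partition the input exactly.

## Registration

The metric is joint-histogram mutual information, `MI = H(F)+H(M)−H(F,M)`,
over a set of fixed-image voxel centres drawn once per round (seeded,
without replacement; 20% of eligible voxels in round 1) and held fixed
across iterations, making the objective deterministic. Moving intensities
are trilinearly interpolated at the transformed sample points;
out-of-image samples are dropped, and fewer than two survivors is an
overlap error. Intensities are binned linearly (32 bins) between each
image's 0.5th–99.5th percentiles, computed once per round, to keep
contrast-agent hot spots from compressing the histogram.

Two bin-assignment modes exist. `"hard"` assigns each sample to one bin —
the textbook estimator, with exact identities (self-MI equals the marginal
entropy; invariance under bin-preserving remaps) that the tests exercise.
The registration default is `"linear"`: each sample is spread bilinearly
over the two adjacent bins on both axes (partial-volume binning). The hard
estimator is piecewise constant in the transform parameters at the scale
of single samples crossing bin boundaries; a derivative-free optimiser
stalls on those plateaus about a millimetre short of the optimum, which
partial-volume binning removes by making the metric continuously
differentiable.

Optimisation is Powell's method over 6 parameters, with rotations scaled
by a 50 mm lever arm so a unit step in any parameter moves a peripheral
point by roughly a millimetre. The optimiser never returns a point worse
than its start. A result is flagged *suspect* when the MI gain is below
10⁻³ or the translation exceeds half the fixed field of view — the
automated surrogate for visual accept/reject; final acceptance remains the
user's call, recorded in the report.

**Two-round scheme.** The global round can lock onto the aortic arch: a
time-averaged PC-MRA and a single-phase CE-MRA place the aorta differently
relative to the chambers. The second round restarts from the round-1
result with full sampling restricted to an axis-aligned box around the LA
and pulmonary-vein segments (mapped into the fixed frame by the round-1
transform, padded 20 mm per side plus half a voxel). The box is run by
default and always when round 1 is flagged.

## Resampling

Masks: nearest neighbour with half-away-from-zero rounding (stated because
voxel-boundary ties otherwise differ across platforms); out-of-bounds is
background; output strictly binary. Scalars: trilinear, zero outside.
Resampling a ~1.2 mm mask to a 3 mm grid perturbs volume by quantisation
(<10% on the phantom atrium) — one reason transferred and reference
volumes differ even under perfect registration.

## Metrics

Dice `2|A∩B|/(|A|+|B|)`; two empty masks are an error, not a vacuous 1 —
degenerate "successes" would hide upstream failures. ASSD averages
nearest-surface distances in both directions between surface-voxel
*centres* in world mm; surfaces are foreground voxels with a background or
out-of-volume face neighbour (6-connectivity; the 26-connected surface is
a superset and is available for surface-fraction analyses). Nearest
neighbours come from a KD-tree, verified against an O(n²) exhaustive
oracle. Bland–Altman uses mean ± 1.96 × sample SD (n−1) of the paired
differences; Pearson r errors out on zero-variance input rather than
returning NaN.

## Hemodynamics

Mean velocity is the pooled mean speed over (voxel, frame) pairs in cm/s —
identical to per-frame averaging for a fixed mask, stated once to remove
ambiguity. Stasis is the time fraction of speeds strictly below the
threshold (default 0.1 m/s), averaged over the mask, in percent; the
per-voxel map is exposed so the scalar is auditable. Stasis thresholds a
continuous quantity, which is precisely why boundary partial-volume voxels
move it more than they move mean velocity — the effect the phantom's
boundary-sensitivity experiment quantifies.

## Synthetic phantom

The generator emulates the study conditions at desk scale: a 1.2 mm
isotropic CE volume and a 3 mm, 25-phase flow series (venc 1.5 m/s) of an
ellipsoidal LA (semi-axes 32/28/22 mm, ≈82.6 ml — a typical dilated
atrium), an appendage lobe, four pulmonary-vein tubes, an aortic arch and
a ventricle. The CE scene is posed at a known rigid transform (default
6/−4/8 mm, 5/−3/2°); the aorta can be displaced further (the decoy) to
reproduce the global-registration failure mode. Intensities are related
non-affinely across modalities (gamma remap, different per-structure
contrasts) so mutual information is genuinely required; the CE volume
carries a smooth multiplicative bias field (amplitude 0.2) and additive
Gaussian noise. Velocity noise is 0.05 m/s per component (a few percent of
venc, typical of clinical phase-contrast data).

The atrial velocity field is a rigid-body swirl (ω = 10 rad/s about the
atrium's axis, peak speed ≈0.4 m/s) scaled per frame by `|sin 2πt/T|` and
damped linearly within 4.5 mm of the wall, giving the low-speed boundary
layer that real chambers show from partial-volume mixing. The veins carry
plug inflow toward the atrium. Two design points deserve emphasis:

* **Irregular vein geometry.** Radii, directions and inflow speeds differ
  per vein. A symmetric vein cross around a near-spherical atrium leaves
  the velocity-visible scene with approximate half-turn symmetries, and
  the registration pose would be ambiguous in the noise-free limit.
* **Closed-form truth.** The in-mask speed is an explicit per-voxel
  formula, so stasis and mean velocity over the truth mask are computed
  exactly from stored parameters; with the defaults they land at ≈53% and
  ≈9.9 cm/s, the clinically typical range. The flow-grid truth mask is
  constructed by the same nearest-neighbour resampling used downstream, so
  truth and pipeline agree voxel-for-voxel by construction.

`perturb_mask` thresholds the signed distance map plus a smooth Gaussian
random field, bisecting the field amplitude to a prescribed Dice (±0.02) —
used to emulate realistic segmentation disagreement (Dice ≈ 0.77).

**What the phantom does not show.** It has no physiologic vortices or
vein jets, no k-space/undersampling artefacts, Gaussian rather than Rician
noise, and piecewise-smooth anatomy. Passing its tests demonstrates the
correctness and identifiability of the implementation under realistic
geometry, contrast and noise — not clinical performance on patient data.
A noise-free phantom is in fact *harder* for histogram MI than a noisy
one: piecewise-constant images make the MI surface rugged with many local
maxima even though its peak stays at the true pose (the tests assert the
peak location at zero noise and pose recovery at realistic noise).

## Problem sizes and tolerances

Validation runs use the default phantom (flow grid 54×62×48, CE grid
135×155×120, 25 phases): large enough that the atrium spans ~28 flow
voxels across, small enough for desk-scale experiments. Pose-recovery
experiments use ten phantoms with misalignments up to 10 mm / 10°;
recovered poses are typically within 0.1 mm / 0.1° and transferred-LA Dice
≈0.99. Oracle comparisons are exact (set equality) or 10⁻⁹-relative;
measured-vs-analytic hemodynamics agree to well under the 2-percentage-
point documentation bound because the generator's field is exact inside
the truth mask. Powell runs with `xtol` 10⁻³ (scaled units ≈ 1 μm /
20 μrad) and `ftol` 10⁻⁵, far below the metric differences that matter.

## Known limitations

* Rigid transfer only; atrial deformation between acquisitions becomes a
  registration residual rather than being modelled.
* Single-resolution optimisation: gross initial misalignments beyond the
  MI basin (several cm) are flagged, not rescued.
* The DICOM reader handles single-series, single-orientation classic
  DICOM; enhanced multi-frame files should be converted to NIfTI first.
* ASSD uses voxel-centre distances, not sub-voxel mesh surfaces; on 3 mm
  grids this quantises distances at the half-voxel scale.
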