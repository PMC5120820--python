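# Methods

`pulse4d` measures the volume of an intracranial aneurysm at every phase of
the cardiac cycle from ECG-gated 4D CT angiography, and asks whether the
resulting volume curve carries pulsatile information or is a product of image
noise. This note describes the measurement model, the synthetic phantom used
to validate it, the statistics, and the numerical choices that were genuinely
open.

## The measurement problem

Aneurysm wall excursions over the cardiac cycle are at or below the voxel
size (0.39 × 0.39 × 0.5 mm in the emulated protocol), so binary voxel
counting cannot resolve them: the information lives in partial-volume
shifts of boundary voxels. The pipeline therefore works with a *sub-voxel*
surface at every phase:

1. **Lumen segmentation.** The contrast-filled lumen is separated from
   cerebrospinal fluid and soft tissue by a Hounsfield band, 160–890 HU by
   default, inclusive at both ends, applied per phase. An axis-aligned
   volume of interest and a seeded 26-connected component filter stand in
   for the interactive clean-up of a clinical workstation.
2. **3D+t model.** Marching cubes extracts the isosurface of the grayscale
   HU field restricted to the (1-voxel-dilated) mask, one triangulated
   surface per phase. The iso-crossing is placed by linear interpolation
   inside boundary voxels, which is where the sub-voxel sensitivity comes
   from. HU above the upper threshold (bone, calcification) are clamped to
   the fill value first.
3. **Neck transfer.** Neck points placed on the phase-0 surface are carried
   to every phase by rigid point-to-point ICP (nearest-neighbour
   correspondences, closed-form Kabsch alignment per iteration, stop when
   the RMS residual changes by < 1e-6 mm or after 50 iterations).
4. **Cut and partition.** The (generally non-coplanar) neck points are
   ordered canonically by angle around the best-fit plane normal and
   triangulated as a centroid fan. Mesh faces are region-grown from the
   face nearest a dome seed point, never crossing an edge that intersects
   the fan; the grown surface is closed with a centroid fan over its rim,
   and the enclosed volume of that closed mesh — a signed-tetrahedron sum
   (divergence theorem) — is the aneurysm volume of the phase.
5. **Statistics.** The 10-point volume curve is min-max normalized and its
   symmetric Hausdorff distance to an arterial pulse-wave template is
   compared, by Welch's t-test, with the distances of random curves drawn
   from the image-noise characteristics (Gaussian, mean 0.5, SD 0.2,
   clipped to [0, 1]).

## The phantom

Patient 4D-CTA data are not distributable, so validation uses a synthetic
phantom with analytic ground truth: a sphere (aneurysm dome) seated on a
straight tube (parent vessel). The neck plane is the plane tangent to the
tube on the dome side; the aneurysm proper is the spherical cap above that
plane and the true neck ring is the circle where the sphere crosses it.

Pulsation drives the *cap volume* linearly with the pulse template,
`V(p) = Vmin (1 + (A − 1) w(p))`, and the sphere radius at each phase is
recovered from the cap-volume cubic by a bracketed root solve, so the
ground-truth amplitude `Vmax/Vmin = A` holds to better than 1e-9. Geometry
is rasterized by supersampled occupancy (3 samples per axis), mapped to HU
(lumen 400 HU on a 40 HU background), blurred with a Gaussian PSF
(σ = 0.4 mm) to create realistic partial-volume gradients, and corrupted
with i.i.d. Gaussian noise of SD = 18% of the lumen attenuation — the noise
level reported for the emulated acquisition. Defaults: 48 × 48 × 36 voxels
at 0.39/0.39/0.5 mm, 10 phases, 8.5 mm dome (mid-range of the 5–17 mm
cohort the protocol targets), 3 mm parent vessel.

Rigid motion, when requested, is rasterized analytically — the moved object
is sampled by the grid. Resampling the image instead (trilinear
interpolation, available as `apply_rigid_motion`) adds an offset-dependent
interpolation blur worth ~1–2% of measured volume, an artifact of image
manipulation rather than of motion; the analytic route keeps the motion
experiment about motion.

The built-in pulse template is an analytic stand-in for a middle-cerebral-
artery waveform (single systolic peak in the first 40% of the cycle, small
dicrotic shoulder, min-max normalized); measured waveform values can be
loaded from CSV instead and are normalized the same way.

What the phantom does *not* emulate: correlated reconstruction-kernel noise
textures, beam hardening, ECG jitter, contrast-bolus dynamics, non-spherical
domes, curved or tapering parent vessels, and neighbouring vasculature.
Passing tests therefore demonstrate the pipeline's correctness and its
noise behaviour under the stated model, not clinical accuracy on patient
data.

## Numerical choices that were genuinely open

- **Iso-value.** The pipeline default is the lower segmentation threshold
  (160 HU). For phantom validation the surfaces are extracted at the
  lumen/background *half-maximum* (220 HU), the unbiased sub-voxel edge
  position for a symmetrically blurred step; at 160 HU absolute volumes are
  biased outward and amplitudes slightly damped, which is documented rather
  than hidden.
- **Noise regularization.** Before thresholding and isosurfacing, the HU
  field is smoothed with a Gaussian of σ = 0.4 mm (matched to the PSF). An
  isosurface of voxel-wise independent 72 HU noise is not a usable surface
  (bubbles, handles, leaks); clinical images get the equivalent suppression
  from iterative reconstruction, so the phantom pipeline supplies it
  explicitly. With it, the per-phase volume noise is ≈ 0.2% and the surface
  is clean down to the smallest studied amplitudes.
- **Neck-point snapping.** Transferred points are *not* re-snapped onto each
  phase's surface by default: vertex snapping quantizes the cut plane by
  ~0.1 mm per phase and surface projection drags the cut outward with the
  inflating dome; both corrupt the 1–6% volume modulation being measured.
  The rigid image of the phase-0 polygon stays within the ICP residual
  (~0.05 mm) of the surface, far inside one voxel diagonal. `snap="vertex"`
  and `snap="surface"` remain available.
- **ICP anchor.** A focus ball around the neck centroid contains mostly dome
  surface, and a pulsating dome's displacement field has a systematic
  component along the neck normal that drags the transferred cut. When a
  dome seed is supplied, the registration instead anchors on the vessel
  side of the phase-0 neck plane, excluding a ball of ring-radius + 1.8 mm
  around the centroid (every below-plane dome point lies within one ring
  radius of the centroid; the margin covers the blur reach), with outer
  reach inner + 3 mm. Under pure inflation this anchor is static; under
  rigid motion it moves with the vessel, which is exactly what the transfer
  should track.
- **Overcut.** For the edge-blocking test the cut fan is scaled outward
  about its centroid by 1.8×, because the lumen surface bulges outside the
  neck polygon between points; the measured cap is still placed at the rim
  of the grown region, so the volume convention is unchanged.
- **Cut geometry.** The "plane connecting the points" is implemented as the
  centroid triangle fan through the actual (possibly non-coplanar) points;
  a `planar` option projects onto the least-squares plane first. Three
  points form a single triangle.
- **Hausdorff embedding.** Curves are embedded as point sets
  {(i/(n−1), v_i)} in the unit square by default. A `value_only` mode drops
  the time coordinate; with the built-in template the random-null mean
  distance is ≈ 0.51 in 2D and ≈ 0.27 in value-only mode, and both modes
  are exposed because published group means of ≈ 0.25 are consistent with
  the value-only convention.
- **Null calibration.** Random null curves are clipped to [0, 1] and not
  re-normalized (group-mean convention). For the *per-curve* percentile
  rule (`classify_curve`, replicate significance), the reference null is
  re-normalized, because the tested curve is min-max normalized first and a
  mismatched null makes the nominal false-positive rate wrong.
- **ICC form.** Two-way random effects, absolute agreement, single rater
  — ICC(2,1) — by default, with ICC(3,1) available; agreement is called
  good above 0.75 (strict). Limits of agreement use the conventional 1.96
  multiplier.
- **t-test.** Welch (unequal variance) everywhere a two-sample t-test is
  called for. A cohort of one curve falls back to a one-sample t-test of
  the null distances against that curve's distance.
- **Degenerate inputs.** Constant curves cannot be min-max normalized and
  are reported as "flat"; zero-variance rating matrices make the ICC
  undefined; empty masks raise before marching cubes; non-watertight
  closed meshes raise with their boundary-edge count.
- **classify_curve thresholds** (flat below amplitude 1.02, pulsatile below
  the null's 5th percentile) are pragmatic conveniences for triaging
  curves, not validated diagnostic criteria.

## Problem sizes

Validation studies run the full pipeline on 48 × 48 × 36 × 10 volumes:
noise-free amplitude recovery at four amplitudes, 50 noise replicates per
pulsating/flat condition, and a 14-aneurysm synthetic cohort — sizes chosen
so the whole suite completes in a few minutes on one CPU while keeping
Monte-Carlo fractions (e.g. the ≥ 90% calibration bound) meaningful.

## Known limitations

- The half-maximum iso rule assumes symmetric blur and a two-material
  interface; calcified walls or adjacent enhancing structures violate it.
- Curvature bias of a blurred isosurface leaves a systematic ~3% absolute
  volume deficit on small domes; ratios (Vmax/Vmin) are much less affected,
  which is why the pulsation statistic is a ratio.
- ICP transfer assumes the vessel near the neck moves rigidly; strong local
  vessel deformation would bias the cut, and the package does not detect
  that failure mode beyond the ICP residual diagnostic.
- The random null models noise as phase-independent; physiological
  confounders (e.g. pulsatile contrast density) are outside the model.
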