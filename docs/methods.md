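# Methods

`ielec` is a headless re-implementation of the standard intracranial
(sEEG/ECoG) electrode localization workflow: align the post-operative CT to
the pre-operative MR, refine clicked contact positions to the center of
their metal artifacts in the CT, compensate ECoG brain shift by projection
onto the leptomeningeal surface, assign anatomical labels from a
segmentation volume, and carry contact positions into a template brain with
a nonlinear registration. Every algorithmic step is verified end-to-end on
a synthetic head phantom with exact ground truth.

## Coordinate model

Voxel indices are 0-based and continuous (integer index = voxel center);
world coordinates are scanner RAS in mm as given by the NIfTI affine
(sform preferred over qform when both are valid, nibabel's convention). No
volume is ever reoriented. Frames are string tags (`ct`, `mr_subject`,
`mr_template`); mixing frames raises instead of silently composing. An
optional per-volume `c_ras` offset (default zero) leaves the door open for
FreeSurfer surface-RAS data; all synthetic data uses scanner RAS directly.
Out-of-bounds resampling fills 0 — the CT/MR background is air — which also
keeps joint histograms well-defined.

## Affine CT→MR registration

Cross-modality alignment maximizes the mutual information (MI) of the
joint intensity histogram (32 equal-width bins per axis over each image's
1st–99th percentile range, plain counts). Optimization is coarse-to-fine
over a pyramid (subsampling factors 4, 2, 1; Gaussian smoothing of
max(factor/2, 1) voxels) with Powell's derivative-free method per stage
(translation 3 params; rigid +3 intrinsic Euler angles about the fixed
volume's world center; affine +3 log-scales, +3 shears). The seed aligns
the two intensity centers of mass unless a manual pre-alignment is given;
a pre-alignment is *required* when fewer than 10 % of fixed voxels map
into the moving field of view.

Two numerical choices matter and were made after observing failure modes
of the naive scheme on the phantom:

* **Off-grid metric sampling.** If the metric is evaluated on the fixed
  voxel grid, any pose that maps fixed voxels onto moving voxel centers
  (in particular the identity rotation) escapes interpolation blur and
  receives a spuriously sharp histogram — MI then prefers grid alignment
  over true alignment by whole degrees. The metric is therefore sampled
  at voxel positions jittered uniformly in ±0.5 voxel (fixed RNG seed, so
  registration stays deterministic); both images are interpolated for
  every candidate pose and no pose is privileged.
* **Finest-level smoothing.** The finest pyramid level is smoothed by one
  voxel. This suppresses the residual anisotropy of the separable linear
  interpolation kernel and the sampling noise of the MI estimate, both of
  which otherwise displace the MI optimum by ~1–2°.

A deterministic 5×5×5 sweep of Euler angles (±12° in 6° steps) at the
coarsest level seeds the rigid stage, because MI is multimodal in rotation.
Powell budgets scale with pyramid level (2 · max_evals · factor function
evaluations per stage); the trace of accepted MI values is monotone within
each level by construction. For same-subject CT→MR the rigid (6-DOF) model
is the appropriate one and is what the recovery analyses use; the full
affine stage remains available for cross-subject or scanner-distorted data,
with the caveat that on low-information images the extra 6 DOF can trade
geometric fidelity for MI.

## Symmetric diffeomorphic (SDR) template registration

Subject-MR→template-MR registration uses a greedy symmetric demons scheme
on intensities rescaled to (0, 1) by their 1st–99th percentiles: at each
iteration the intensity difference force with the symmetric gradient
(mean of fixed and warped-moving gradients) and Thirion normalization is
smoothed by a Gaussian of `field_sigma` (default 2 mm) and added to the
displacement field, and the accumulated field is smoothed by the same
kernel (fluid + diffusion regularization; without the second smoothing the
field accumulates noise and the iteration diverges). Levels mirror the
affine pyramid with default iteration counts (10, 10, 5) — on the phantom
more iterations begin to fit noise rather than signal, so the default is
also the accuracy optimum there.

The forward field (fixed grid → affine-aligned moving space, in mm on the
fixed grid) carries the registration; the backward field is computed from
it by fixed-point inversion (25 iterations), which makes the
forward∘backward round trip identity to well under half a voxel by
construction — the practical content of the "symmetric diffeomorphic"
contract. Point warping applies the pre-affine and adds the trilinearly
interpolated field; points outside the field grid fall back to the affine
map and are flagged.

## Snap to center

Given a seed near a contact, the brightest voxel within `radius` (default
5 mm; ties → closest to seed, then lexicographic) anchors a region grown
over 26-connected neighbors admitting a voxel whenever *any* admitted
neighbor has intensity ≥ its own (so intensity is non-increasing along
some path from the peak), bounded below by `intensity_floor` (0.25 × peak)
and laterally by `max_region_radius` (5 mm). The contact position is the
intensity-weighted centroid of the region's voxel centers in world mm.
The admitted set is a closure over descending edges and therefore
independent of traversal order; a queue-based search and an iterate-to-
fixed-point formulation are both implemented and verified identical.

The search radius must stay below roughly half the contact spacing or the
peak search can capture a neighboring contact: with the phantom's 5.25 mm
shaft pitch the recovery analyses use radius 2.5 mm, and the end-to-end
pipeline uses 2.2 mm (half the closest post-shift grid spacing). All
distances are computed in world mm, so anisotropic voxels are handled.

## Brain-shift projection

ECoG grids sink below the pre-operative pial surface during craniotomy.
Correction moves each selected contact to the exact nearest point on the
leptomeningeal mesh, computed by vectorized point-to-triangle distance
(barycentric region classification) over all triangles — exact by
construction and fast at phantom mesh sizes (~5 k triangles), so no
spatial acceleration structure is used. Ties report the lowest triangle
id. Projection is idempotent and leaves unselected contacts untouched;
projected pairs closer than 1 mm are logged, not resolved.

The leptomeningeal surface itself is produced from a closed pial mesh by
Laplacian smoothing with a non-shrinking constraint: after each relaxation
step every vertex's radial distance from the surface centroid is clamped
to at least its original value. On star-shaped (head-like) surfaces this
fills sulci outward while leaving gyral crowns fixed, so the result
encloses the input and changes enclosed volume only by the small sulcal
volume. A plain volume-renormalized smoothing cannot satisfy both
requirements at once: rescaling to the input volume necessarily pushes
the smoothed surface slightly inside the original convex parts.

## Anatomical labeling

Each contact samples the integer segmentation in a world-mm ball (default
radius 2 mm; radius 0 = nearest voxel); label fractions are voxel counts
over the total, sorted descending with ties broken by lower label id.
Positions outside the grid are Unknown. Shaft sequences order contacts by
ascending number — contact 1 is the deepest, at the electrode tip.

## The phantom

All inputs are generated from analytic scene functions on a 64³ grid at
1 mm (small enough that the full pipeline runs in minutes on one CPU),
with a single integer seed driving every random element, so identical
specs give bit-identical data. The head is a mild triaxial ellipsoid
(brain semi-axes 25 × 23 × 21 mm inside a 2 mm skull shell with angular
thickness variation, fat rim outside): a sphere would leave rotation
unconstrained, and a smooth shell carries almost no orientation
information at the 1° scale. Shared anatomy that anchors cross-modality
registration in real heads is modeled explicitly — paired lateral
ventricles, a frontal sinus punching through the skull ring, and a smooth
intra-brain texture field that modulates the MR directly and the CT
through a nonlinear map (statistical dependence is all MI needs). CT noise
is σ = 0.05 on a scale where the skull is 1.0 ≈ 1000 HU, i.e. an order of
magnitude *noisier* than clinical CT; electrode contacts are Gaussian
blobs (σ 1.1 mm) of amplitude 5 — metal contrast is enormous in reality,
and the spec-level requirement blob SNR ≥ 5 holds with two orders of
margin.

Ground truth is stored for everything: the rigid CT misalignment (rotation
5–15° about the head center plus a ≤3 mm center shift, within the bounds a
scanner repositioning produces), the sEEG shaft (10 contacts, 5.25 mm
pitch, threaded along the head's long axis), the ECoG grid pre- and
post-shift (4×4, 6 mm pitch, depressed 3 mm along the local surface
normal — the nearest-point projection of the depressed contact is then the
pre-shift position, exactly), the smooth sinusoidal template deformation
(amplitude 3 mm, wavelength 48 mm; max gradient 0.39, hence invertible,
with the inverse computed to machine precision by fixed-point iteration on
the analytic displacement), per-contact generating labels, and meshes.

What the phantom does *not* model — and what passing tests therefore do
not show — includes: gyral/sulcal cortical geometry beyond shallow
sinusoidal dents, CT metal streak artifacts and beam hardening, MR bias
fields and geometric distortion, partial-volume mixtures at tissue
interfaces beyond smooth sigmoid edges (width 0.7 mm), non-rigid
CT-to-MR discrepancies, and electrode wires/cables. Results on clinical
data will be correspondingly less accurate, particularly for snap
(streaks), projection (real leptomeningeal geometry) and labeling
(segmentation error dominates in practice).

## Verification scales

The recovery analyses run at the phantom's native scale: five misaligned
phantoms for rigid registration (each ≤1 min), one ~90° case exercising
the manual pre-alignment path, the 10-contact shaft with seeds jittered
uniformly within 2 mm, 20 random volumes for region order-independence,
1000 random points against an independent nearest-point oracle
(trimesh), the full 64³ field for SDR recovery, and two complete pipeline
runs compared byte-for-byte for determinism. `scripts/acceptance.py`
recomputes the same figures from scratch (three rigid cases) with all
randomness derived from its `--seed`.
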