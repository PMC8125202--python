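# Methods

This note documents the measurement model, the numerical choices, the
synthetic phantom used for validation, and the known limitations.

## Coordinate conventions

Volumes are indexed `values[k, r, c]` with `k` the axial slice numbered
superior → inferior, `r` the row (y) and `c` the column (x). Physical mm
coordinates are `origin + index · spacing`, so the local z coordinate
*increases inferiorly*; "up" means decreasing z. DICOM series are sorted by
descending patient z to obtain this order. Voxel indices are 0-based and all
index intervals half-open. CBCT grey values are linearly rescaled
("pseudo-HU") but not quantitatively calibrated; the method uses only the
contrast ordering air < soft tissue < bone.

The reference slice uses in-plane coordinates (u, v): u horizontal
(`col · du`), v vertical (`row · dv`, `dv = dz`, increasing downward). The
mapping to volume coordinates is an isometry through the plane anchor and
azimuth. Which u direction is *frontal* (anterior) cannot be derived from
index space alone, so it is resolved from the user-supplied joint laterality:
frontal = +u for a left joint, −u for a right joint. This is a convention of
this implementation; if a scanner's patient orientation differs, swap the
laterality flag.

Plane azimuths are normalised to [−90°, 90°) rather than [0°, 180°), so a
section direction fluctuating around 0° cannot flip the u axis between runs.

## Denoising

The curvature-flow filter evolves iso-intensity level sets under mean
curvature; homogeneous regions flatten while extended bone interfaces, which
have low curvature, are nearly stationary. Defaults: 10 iterations with a
dimensionless time step of 0.01 (config keys `denoise.*`). The PDE runs on
the **voxel grid** (unit spacing): the explicit scheme's stability bound and
the meaning of the time step are grid-referred, and running it in physical mm
at 0.3 mm voxels would implicitly multiply the step by 1/0.3² ≈ 11 and
visibly erode thin structures. Denoising is applied after VOI cropping; this
only affects voxels within one stencil of the VOI border.

## Per-slice mixture segmentation

Each axial slice's histogram near the TMJ shows a dominant low (air) peak
with smaller soft-tissue and bone populations to its right. A K = 3
component 1D Gaussian mixture is fitted to every slice separately by EM:

* deterministic initialisation at the 10th/50th/90th percentiles of the
  slice values, equal weights, and per-component variances from the
  nearest-mean partition (a single pooled variance lets the components
  overlap so strongly that EM stalls in a merged optimum);
* a second deterministic start (k-means) is run as well and the fit with the
  higher log-likelihood is kept. On slices where one tissue class dominates
  — notably the bone-heavy reference slice — the percentile start can place
  two components inside that class; the k-means start does not;
* convergence tolerance 1e-4 on mean log-likelihood, variance floor
  1.0 pseudo-HU² (as EM regularisation).

A pixel is bone when its maximum-posterior component is the component with
the highest mean. Postprocessing per slice: delete 8-connected components
touching the ROI border (other skull bone always enters from the VOI edges),
then replace each remaining component by the filled convex hull of its pixel
centers (the condyle is nearly convex; its trabecular interior segments
poorly). Across the stack, the largest 26-connected 3D component is kept.
Size ties are broken by raster order (smallest first index), which is
deterministic. Hull filling is idempotent as long as filled hulls do not
merge previously distinct components.

## Reference plane and slice

Per head-bearing slice, the minimum-area enclosing rectangle of the
component's pixel centers (rotating calipers over the convex hull) is
computed; for each *shorter* side, the contact point is the mean of the
pixel centers within 0.75 in-plane voxel diagonals of the side's line,
projected onto it (the tolerance guards rasterisation). For a square
rectangle the side pair whose contact points are farther apart is used,
consistent with the longest-section objective. Collinear slices fall back to
the endpoints of the pixel set's diameter. The longest section is the
globally most distant pair among all collected contact points (endpoints may
come from different slices), and π_V is its vertical perpendicular bisector
plane.

The reference slice is obtained by rotating the whole volume about the
vertical axis through the plane anchor (per-slice bilinear resampling,
out-of-volume fill −1000) so π_V lands on a grid column; the anchor is
snapped to the nearest column and the sub-voxel residual is absorbed in the
resampling translation. The slice is re-segmented with the same mixture
model — fitted on in-volume samples only, since the constant fill value
would add a spurious histogram peak — without hole filling and without the
largest-component restriction, so the fossa is retained. Two derived
intensity levels are stored with the slice: the *soft level* (soft-tissue
component mean) and the *bone threshold* (the analytic decision boundary
between the soft and bone components).

## Landmarks and gap widths

*P_TMJh*: on the uppermost head-bearing axial slice, the plane's trace is
sampled against the head mask; the midpoint of the longest intersection run
gives u. Because slice i₀ holds head bone and slice i₀−1 does not, the apex
v is estimated at the interface half a slice above i₀ (a pure `i₀·dz`
convention carries a systematic half-voxel bias).

*P_TMJa*: marching straight up the reference-slice mask from *P_TMJh*, the
head's own bone run is skipped and the first bone pixel after at least one
non-bone sample is taken; the surface is then refined to sub-voxel precision
by the intensity crossing of the bone threshold between that pixel and the
gap pixel below it. r_C is the Euclidean (purely vertical) distance.

**Tangent sweep.** Half-lines from *P_TMJa* at angle θ from the downward
vertical are sampled bilinearly at half the minimum in-plane spacing. The
distance to the first slope, d(θ), is the first positive local maximum of
the profile's central-difference derivative that exceeds 25 % of the
profile's maximum absolute derivative, at least 2 samples from the origin
(which skips the origin's own bone-exit peak). Two robustness rules are
applied, both consequences of what the edge is supposed to mean
(a soft-tissue → bone crossing):

* profile values are clipped from below at the soft level before
  differentiation, so that a later soft → air drop (air cells, out-of-volume
  fill), whose contrast is several times the soft/bone contrast, cannot
  dominate the relative threshold;
* a candidate edge counts only if the profile's median over ~1 mm past the
  peak actually reaches the bone threshold. A half-line that merely grazes
  the head boundary produces a partial-volume bump whose derivative peaks
  but whose values never reach bone; without this check such grazes postpone
  the d(θ) step past the sweep limit at coarse voxel sizes.

The sweep runs 0–50° in 5° steps; the first consecutive pair whose increment
exceeds max(1.0 mm, 3 × median of the increments seen so far) — or where d
becomes undefined — brackets the tangent; the bracket is re-swept at 0.5°
and θ^T is the mean of the fine bracketing pair. The contact point is the
bone-entry point at the last angle still crossing the head (the line exactly
at θ^T may already miss the head after discretisation; the error is bounded
by the fine step). The gap width is then measured from the contact point
along the perpendicular to the swept line, directed away from the head
component's centroid, by marching the reference-slice bone mask to the first
fossa pixel; the surface is taken midway between the last gap sample and the
first bone sample. Measuring against the classified mask rather than a raw
intensity threshold keeps the two gap ends consistent with the segmentation.

A measurement with any width below one voxel is flagged degenerate (condyle/
fossa contact) rather than rejected.

**Applicability bound.** With the sweep capped at 50°, a circular head of
radius R requires arcsin(R/(R+d)) < 50°, i.e. an upper gap d ≳ 0.31 R, for
the tangent to lie inside the sweep; flatter (non-circular) condyle tops
relax this considerably. The cap is a configuration value (`sweep.theta_max`).

## Phantom

The generator emulates the geometry and intensity regime the measurement is
designed for, not CBCT physics:

* condyle: sphere (R, default 6 mm) or ellipsoid (a ≥ b, c; long-axis
  azimuth φ), plus a vertical cylindrical neck (0.55 b radius) continuing
  inferiorly from the equator, so every slice below the head contains bone;
* fossa: the whole region above the condyle equator outside the gap-inflated
  condyle surface (uniform gap g, optionally with an in-plane offset of the
  fossa centre for eccentric gaps). Because this region reaches the VOI
  borders on every axial slice it is removed by border-component deletion
  during head segmentation — exactly how real temporal bone, connected to
  the rest of the skull, is discarded — while it survives on the reference
  slice;
* an air slab (default 5 mm) along the +y edge keeps all three intensity
  classes present on every slice (standing in for the ear canal / mastoid
  air); the gap itself is soft tissue;
* intensities: bone 180, soft −60, air −950 pseudo-HU with additive Gaussian
  noise (default σ 25) — deliberately low-contrast bone, matching the
  observation that pseudo-HU near the TMJ barely exceeds 200, so the mixture
  segmentation is actually exercised;
* options: an internal soft cavity (exercises hull filling) and a
  border-touching distractor block (exercises border removal).

Ground truths (r_C, per-side gaps, tangent angle, plane azimuth, section
length) are computed from the analytic membership functions — closed form
where available (tangent from an external point to a circular section;
per-side truths are only defined when b = c so the reference cross-section
is a circle), fine-step ray casting (5 µm) otherwise — and are independent
of the noise seed. The returned VOI honours the assumption that its
uppermost slice lies above the fossa roof.

What the phantom does **not** model: trabecular texture, beam hardening,
scatter, metal artefacts, inter-device grey-value drift, head-pose error and
genuinely non-convex condyle shapes. Passing phantom tests therefore
demonstrates the geometric and statistical machinery, not robustness to
every clinical scan.

A separate helper builds a finely sampled (0.05 mm) synthetic reference
slice with a circular head and exactly placed *P_TMJa*: at 0.3 mm voxels a
single-voxel error in *P_TMJa* moves arcsin(R/(R+d)) by ≈ 1.2°, so the
±0.5° check of the tangent machinery is meaningful only free of landmark
discretisation.

## Validation problem sizes

The property suite runs the full pipeline on 80³ and 128³ voxel phantoms at
0.3 mm isotropic spacing (three noise seeds for gap recovery, four condyle
orientations for azimuth recovery, one rotation pair for invariance), the
tangent analytics on 0.05 mm synthetic slices, EM recovery on 3 × 10⁴-sample
mixtures, and the geometric primitives against exhaustive oracles on 50
random convex masks.

## Known limitations

* The dorsal/frontal label assignment is a laterality convention (see
  above), not derivable from the data.
* Landmark accuracy is half a voxel at best in v; r_C inherits up to one
  voxel of combined discretisation error.
* The sweep cap interacts with deep, nearly spherical heads (see
  applicability bound); clinically observed tangent angles (~30°) are well
  inside it.
* Per-slice EM can fail when bone/soft contrast collapses; the variance
  floor and dual initialisation mitigate but cannot remove this.
* Multi-frame (enhanced) DICOM, device-specific HU calibration and
  head-pose (Frankfurt-plane) correction are out of scope.
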