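# Methods

`midseg` automates the delineation of the midbrain nuclei — the
neuromelanin-rich substantia nigra (NM/SNpc), the iron-rich SN, the red
nucleus (RN) and the subthalamic nucleus (STN) — from a paired
neuromelanin-sensitive magnitude volume and a quantitative susceptibility
map (QSM) acquired in the same multi-echo magnetization-transfer GRE
session. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not
show.

## Susceptibility reconstruction

The QSM chain maps wrapped GRE phase to tissue susceptibility in ppb:

1. **Unwrapping.** Best-path 3D unwrapping (Herraez-family algorithm via
   scikit-image), masked to the brain. Output is congruent to the input
   modulo 2π voxelwise.
2. **Background-field removal (SHARP).** Spherical-mean-value filtering
   with a 6-voxel sphere removes harmonic fields sourced outside the brain,
   followed by truncated deconvolution of the SMV operator at threshold
   0.05. The result is valid on the mask eroded by the kernel radius.
3. **Dipole inversion (TKD).** Division by the unit dipole response
   `D(k) = 1/3 − k_z²/|k|²`, replaced by `sign(D)·0.1` where `|D| < 0.1`.
   The iterative variant runs 4 passes of cone replacement: the image is
   thresholded at 0.1·max|χ|, forward-transformed, and its k-space values
   substituted inside the ill-conditioned cone `|D| < 0.1` while measured,
   well-conditioned k-space stays fixed. On the 64³ sphere phantom this
   raises interior recovery from ~90 % (plain TKD) to ~100 % and removes
   streaking variance outside the source.

Units: the local field is carried in radians and scaled once at inversion
with γ = 2.675×10⁸ rad/s/T, B0 = 3 T, TE = 15 ms (configurable). The SMV
sphere is defined in voxel units; the validation grids are isotropic.

## Dynamic-programming boundary refinement (DPA)

A closed initial boundary is refined slice-wise to lock onto image edges.
`n` profiles are erected along outward normals of the (lightly smoothed)
boundary, each carrying `2R+1` candidates at integer offsets
(`R = 6` px on the ×4-zoomed working grid). A cyclic shortest path picks one
candidate per profile, minimizing

* node cost `−g/max(g)`: `g` is the outward directional gradient sampled
  with half-pixel central differences and bilinear interpolation (plus a
  10⁻⁶-scale bias toward the brighter side that resolves the exact
  two-candidate tie a sharp step edge produces);
* pair cost `|Δoffset|/R` between neighboring profiles (stretch);
* triple cost `α·κ`, with `κ` the Menger curvature of three consecutive
  candidate vertices — the local radius-of-curvature constraint. `α`
  defaults to 0.10; raising it toward 0.20 visibly smooths the result when
  gradients are ambiguous (at high CNR the data term dominates and `α` has
  little leverage — the monotone-smoothing check therefore runs at CNR 3).

The cyclic program is solved **exactly**: the first two offsets are
enumerated and a (previous, current) pair-state dynamic program propagates
the triple terms, matching brute-force enumeration over all cyclic paths
(verified on random graphs). Ties prefer smaller |offset|. The solver is a
compiled (numba) kernel.

Design choices that proved load-bearing:

* **Profile density ~1 per boundary pixel** (`max(64, perimeter)`).
  Coarser sampling (a profile every 2 px) cannot represent single-pixel
  staircase corners, which breaks exact area recovery on rectangular
  phantoms.
* **Subpixel vertex snap.** After the discrete solve, every vertex slides
  to the continuous maximum of the directional gradient within ±0.6 px
  along its normal. This puts vertices exactly on step edges (and corners),
  and at the center of interpolation ramps — without it, either corners are
  chamfered off or ramped edges bias the boundary outward.
* **Exact pixel-boundary polygons.** After each iteration the solved
  contour is rasterized (pixel centers inside-or-on the polygon) and
  re-traced as the exact outline of the pixel set (vertices on pixel
  corners), so contour area ≡ pixel count and the iteration is free of
  cumulative rasterization drift. Concavities narrower than the profile
  spacing are closed.
* **Background offset (NM only).** For NM work the image is lifted by
  +1000 wherever it exceeds the intensity floor and zeroed below, turning
  the floor level-set into a steep, easily tracked cliff; this speeds
  convergence and keeps a small search radius safe. Susceptibility maps are
  *not* offset: their Otsu floor sits well below the nucleus mean, and an
  offset would glue the boundary to the outer foot of the interpolation
  ramp instead of the true edge.
* **Search-region constraint.** Candidates outside an allowed mask get
  infinite cost. In the pipeline the allowed region is the mapped template
  boundary dilated by the search radius, minus the other structures' mapped
  boundaries — this is what operationalizes "the RN boundary prevents SN
  leakage" and the template-based SN/STN partition.

Iterated refinement (5 passes by default) re-applies the floor (optionally
re-estimated by Otsu over the region plus a search-radius band, so both
intensity classes stay represented after convergence), re-rasterizes,
thins the supported region to a centerline — used to orient normals
outward, which stays well defined for crescent shapes — rebuilds the graph
and re-solves.

Thinning is a direct vectorized implementation of the classic two-
subiteration Zhang–Suen scheme with batch deletion (validated against a
naive loop reference); note the resulting skeletons are 8-connected.

## Thresholding rules

* NM floor = background mean + 4 × SD, where the SD is a cohort calibration
  constant: the mean of per-subject background SDs measured on the zoomed
  working images of the template cohort (the averaged template itself is
  noise-suppressed and would understate it). Background statistics come
  from background ROIs mapped from the template.
* QSM preparation inside a mapped boundary: negatives are zeroed, Otsu
  (256 uniform bins, between-class variance; flat maxima resolved to the
  plateau center) is computed inside the ROI and capped at 30 ppb, and the
  starting boundary shrinks to the largest connected component of the
  surviving support. The DPA then runs on the negatives-zeroed map itself;
  the capped Otsu threshold governs only the starting-boundary shrinkage.
* Volume gates for reporting: NM contrast % = 100·(S − bg)/bg with gates
  {5, 7, 8} %, susceptibility gates {50, 75, 100} ppb; volume loss is
  1 − V_gated/V_ungated and is non-decreasing in the gate by construction.

## Template construction and segmentation

The template lives in the space of one designated best case. Construction:
global rigid → affine → B-spline registration of every subject to the best
case over the central 50 slices; a 16-slice midbrain crop anchored so the
red nucleus sits on crop slice 10 (1-based; if the RN support spans two
slices the lower is used, if three the middle); a local deformable
refinement of the crop; voxelwise averaging (the average acts as a
probability map); ×4 in-plane zoom and slice interpolation to 1/12 spacing
(16 → 192 slices, 2 mm → ~0.167 mm) to form the drawing grid. Boundaries
(operator drawings, or phantom ground truth) are then finalized with the
DPA on the averaged images — with a reduced search radius of 3 px, since
the drawings are trusted and the averaged edges are blurred by residual
alignment error.

Segmentation of a new subject is fully automatic: global map (to locate the
RN and crop), ×4 zoom, local map, template boundaries pushed through the
local transform into subject space, NM-floor / QSM-Otsu preparation, and
per-slice DPA refinement in the order RN → SN (RN excluded) → STN (both
excluded); final masks are made pairwise disjoint by that order. The VTA is
carried by mapping alone (it has no reliable intensity edge) and the SNpc
is derived as `(NM \ VTA) ∩ SN`.

Registration numerics are pluggable. The shipped SimpleITK backend uses a
dense mean-squares metric (deterministic, no sampling):

* global stages: rigid and affine (multi-resolution, regular-step gradient
  descent) plus a coarse free-form B-spline with line-search gradient
  descent, its through-plane coefficients frozen — on 2 mm slices a
  z-deformation is mostly noise-driven and corrupts the slice anchoring;
* local stage: an in-plane rigid initialization followed by a
  symmetric-forces demons displacement field restricted to in-plane motion,
  estimated on a combined channel (NM percent-contrast + 0.08 × χ), since
  both contrasts come co-registered from one acquisition and carry
  complementary edges. The transform is a physical-space mapping estimated
  on the native crop grid and applied unchanged to the ×4-zoomed boundary
  grid. A free-form B-spline stage is available behind the same interface
  but is an order of magnitude slower per iteration on these blocks and
  ill-conditioned in the slice direction, so the pipeline defaults to
  demons.
* slice-offset search: the global map anchors the crop to about one slice;
  the local stage therefore tries crop windows shifted by {−1, 0, +1}
  slices and keeps the fit with the smallest residual.

Transforms are invertible: linear stages exactly, deformable compositions
via iterative displacement-field inversion (round-trip error < 0.25 px on
midbrain points for the warps used here).

## Synthetic data

The phantom module emulates the study conditions rather than any real
dataset:

* **Shape phantoms** (rectangle 35×40 px → area 1,400; moon; cashew; disk)
  with two intensity levels and Gaussian (optionally Rician) noise at
  CNR = (I_in − I_out)/σ, default 7.
* **Midbrain phantoms**: 64×64×64 voxels at 0.67×0.67×2 mm. Per
  hemisphere: a tapered crescent-like SN (χ ~ N(125, 20) ppb, matching
  healthy-elderly SN values near 125 ppb), an ovoid RN (N(100, 15)) three
  (or two) slices thick, a small STN (N(110, 12)) abutting the SN
  anterosuperiorly *without* an intensity seam — only the template boundary
  separates them, as in real anatomy — an NM-rich region at 5–10 % contrast
  over a 1,000 a.u. background with 1 % noise, a Y-like VTA, and background
  boxes. Painted (non-truth) context — brain envelope, ventricles, a
  pons-like body and a posterior band — gives the global registration the
  kind of whole-head anatomy real NM-MRI has; without it the slice
  anchoring is underdetermined. Per-subject variation: a smooth random
  in-plane warp (RMS 1.2 px), rigid jitter (≤3°, ≤2 px), an integer slice
  shift (≤2), an extra independent STN displacement (≤1.5 px, reflecting
  the STN's known localization variability), and intensity jitter. Truth
  masks are warped analytically and images are painted *from* the warped
  masks, so image edges and ground truth agree exactly.
* **Dipole-forward phantoms**: wrapped phase from a known χ map (optionally
  plus an out-of-mask source for exercising SHARP).

Everything is deterministic under a fixed seed. An optional nigrosome-like
low-χ notch inside the SN exercises gap robustness.

**What passing tests show — and do not show.** The phantoms have piecewise
constant tissue classes, in-plane-only anatomical variability, Gaussian
noise and exact co-registration of NM and χ volumes. Real data add partial
voluming, through-plane variability, B1/coil shading, flow and motion
artifacts, and imperfect inter-echo alignment; the synthetic DICE values
(SN ≈ 0.97, RN ≈ 0.92, NM ≈ 0.93, STN ≈ 0.95 on a 10-subject held-out
cohort, with the STN the most variable) are therefore upper bounds on
real-data performance, and the cohort-scale agreement reported for real
data is mirrored only qualitatively. One synthetic subject in ten draws a
locally large (~6 px) warp that defeats the local registration — the
cohort-mean criteria absorb it, which is the intended reading.

## Problem sizes and runtime

The validation cohort uses a 5-subject template and 10 held-out subjects at
the sizes above; building the template takes ~1 minute and each subject
~25 s on one CPU, dominated by the per-slice DPA solves (a few hundred
exact cyclic programs of ~200 profiles × 13 offsets each).

## Known limitations

* Per-slice 2D refinement: no through-plane surface coherence beyond the
  crop anchoring and the mapped template.
* The 30 ppb Otsu cap and the 4·SD NM floor are fixed rules; on data whose
  background statistics differ strongly from the calibration cohort they
  need re-calibration.
* The demons local stage assumes the NM and χ volumes are co-registered and
  similar in structure to the template crop; gross pathology (e.g. severe
  SN depletion) would call for the B-spline stage with regularization
  tuning.
* `mask_to_contour` traces outer boundaries only; interior holes (e.g. a
  nigrosome gap fully enclosed by SN) are filled in the contour
  representation.
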