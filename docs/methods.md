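# Methods

This note records the models, conventions and numerical choices behind
`dosemimic`, and what the synthetic test bed does and does not establish
about real clinical data.

## Grid model and geometry

All fields live on regular 3D grids with voxel centers at
`origin + index · spacing` (mm, 0-based, axis order x/y/z). Volumes are
voxel counts times the voxel volume. Margin expansion is Euclidean
dilation on voxel centers: a voxel joins the expanded structure iff its
center lies within the margin of some occupied voxel's center. This makes
the operation exactly checkable against lattice enumeration, at the cost
of discreteness: on a grid coarser than the margin (e.g. a 3 mm cord PRV
margin on a 4 mm test grid) the dilation adds nothing, which is the
correct answer under this convention. The default grids are 2 mm
isotropic, 128³.

Resampling is trilinear at the target voxel centers, with 0 Gy outside the
source extent — dose outside the scanned volume is unknowable and zero is
conservative for body-restricted metrics. Trilinear interpolation is exact
on globally linear fields, which the tests exploit.

## Plan normalization

Every dose distribution is reported after rescaling so that 50% of the PTV
volume receives 100% of the prescription (60 Gy in 30 fractions by
default). D50% is the exact order statistic (the ⌈N/2⌉-th hottest voxel),
not an interpolated percentile, so normalization followed by re-evaluation
returns the prescription exactly. The predicted dose is normalized before
band extraction, and the optimizer's achieved dose is normalized again
after resampling to the native grid; the two passes are independent.

## Isodose-band structures and objectives

Band intervals are half-open in normalized dose, `low% ≤ d < high%`, so
the adjacent low-dose bands (5.0–8.3 / 8.3–33.0 / 33.0–40.0) partition
their range; the deliberately overlapping mid-dose bands (60–80, 70–90,
80–95) are kept exactly as templated. "Band" means dose-interval
membership of the voxel — disconnected components included, no hole
filling — which is the simplest testable reading; a topological
"interior of the isodose surface" reading would differ for non-convex
dose shapes. The PTV band structure is the *complement* construction: PTV
minus the voxels lying in 99–110% of prescription (the under/over-dosed
part of the target the optimizer must fix). Band structures may be empty
on well-behaved inputs (e.g. 103–110% after normalization); empty
structures contribute zero penalty with a warning rather than failing.

Objectives are one-sided quadratic penalties,
`priority / N · Σ max(0, d − D)²` for Upper (volume 0) and the mirror
image for Lower (volume 100), summed without priority normalization —
the conventional differentiable reading of upper/lower dose-volume
objectives with priority weights. Only the point forms (volume 0/100) are
supported; the shipped mimicking template uses nothing else. The
DVH-prediction template carries its model-generated "line" objectives and
the normal-tissue objective (distance 0.5 cm, 100%→40%, fall-off 0.25 cm)
as metadata only: they parameterize a proprietary falloff cost that the
toy optimizer does not evaluate. Its two cord rows print no priority in
the source template; 100 (the target-row Lower priority) is the default
used here.

## Beamlet engine and optimizer

The dose model is deliberately simple: parallel (non-divergent) beamlets
on a two-half-arc geometry (181°→0° for right-sided targets, 0°→179° for
left-sided), water-equivalent medium, per-beamlet kernel
`exp(−μ·waterpath) · exp(−r²/2σ²)` truncated at 3σ, with the water path
ray-marched through the Body mask upstream of each voxel. Defaults:
μ = 0.005 mm⁻¹ (a 6 MV-like effective attenuation), σ = 4 mm, 5 mm leaf
rows and lateral bins covering the PTV cross-section plus a 15 mm margin,
16 control points. The field-margin restriction means the engine cannot
reproduce a large low-dose bath far from the target; upper objectives on
the low-dose bands are therefore easy to satisfy, and the mimicking
fidelity claim is about the mid/high-dose region.

The optimizer is projected first-order descent with backtracking halving
(40 halvings max) and non-negativity projection, iteration cap 200,
relative-decrease stop 10⁻⁶. Acceptance of a step requires the penalty
not to increase, so the recorded trace is non-increasing by construction;
a failed line search terminates the run. Initialization is uniform weights
scaled so the mean dose over Lower-objective voxels starts at the
prescription (a random initialization is available and is the only use of
the seed). Optimization runs on a 2-fold decimated copy of the native grid
(every second voxel per axis, so 4 mm from the default 2 mm phantom) —
voxel centers are preserved, masks are subsampled exactly, and the
achieved dose is resampled back to the native grid before the final
normalization. This keeps the default 128³ case to seconds on one CPU.
Aperture conversion opens each leaf row over the longest contiguous run of
lateral bins exceeding 20% of the control point's peak beamlet weight and
assigns the mean retained weight as the control point's MU.

## Evaluation suite

* DVH curves are cumulative ("volume receiving at least d"), default bin
  0.01 Gy; DVH *parameters* are computed from the sorted voxel doses
  directly (exact order statistics, no interpolation, no binning bias).
  D_x% is the largest dose covering at least x% of the volume; D_xcc
  errors out when the structure is smaller than x cc; V_xGy counts
  `d ≥ x`.
* iDSC is computed over the full common grid (not body-restricted), at
  thresholds 1–95% in 1% steps. Two empty isodose volumes score 1.0
  (agreement of empties — the ratio is otherwise 0/0); exactly one empty
  scores 0.0.
* The voxel-wise dose difference is body-restricted, normalized to the
  prescription and expressed in %; a voxel passes threshold t when
  `|DD| < t` strictly ("below"), thresholds 1–20%, voxels pooled across
  cases before the rate is taken.
* MCSv follows the VMAT adaptation of the modulation complexity score:
  per-bank LSV over in-field leaves (in-field = gap > 0.5 mm), AAV against
  the arc-maximal per-leaf opening, adjacent-control-point averaging,
  segment-MU weighting. Segment MU between adjacent control points is the
  mean of the two control-point weights (DICOM cumulative meterset weights
  are converted to per-control-point weights by forward differences on
  read). The score is clamped to [0, 1] against float round-off at the
  bounds.
* The Wilcoxon signed-rank test drops zero differences, mid-ranks ties,
  and for n ≤ 25 computes the two-sided p from the exact sign-flip null
  via dynamic programming over doubled ranks (half-integer mid-ranks stay
  exact); above n = 25 it uses the normal approximation with continuity
  correction and the tie-adjusted variance Σrᵢ²/4. The Bonferroni level is
  α/m; with the standard 12-parameter DVH panel, 0.05/12 ≈ 0.0042.

## Synthetic phantoms

Anatomy is assembled from analytic solids (ellipsoids and tubes)
rasterized by voxel-center membership, with seeded ±3 mm jitters of organ
centers: elliptical body, two lung ellipsoids, a spherical PTV inside the
selectable tumor-side lung with the CTV a 5–7 mm margin inside it
(default 6 mm), esophagus tube, heart ellipsoid, spinal-cord tube with a
3 mm PRV. Generated sets always satisfy the containment invariants
(CTV ⊆ PTV ⊆ Body, cord ⊆ PRV, lungs disjoint from cord) or fail loudly.
The default PTV volume (~113 cc) sits inside the 40–990 cc clinical range
the generator enforces.

The reference dose field is closed-form, not a physics simulation: a
98–104% plateau over the PTV (inside the clinical 95–107% window before
normalization), exponential falloff with a 12 mm default scale outside,
and a low-dose bath (default 8% of prescription) weighted toward the
tumor side by a smooth lateral tanh (ipsilateral weight 1, contralateral
≈ 0.25), zero outside the body. Perturbation modes produce pairs with
*known* divergence for calibrating the difference metrics; in particular
the uniform shift of s% yields MAE exactly s, and the smooth-noise mode
scales a periodically smoothed Gaussian field to unit mean absolute value
(stationarity makes the calibration hold on the body sub-region) and
flips the local sign where a shift would drive dose negative, preserving
the perturbation magnitude.

Synthetic VMAT plans interpolate gantry angles across the half-arc and, at
modulation level m ∈ [0, 1], shrink and shift each leaf pair by uniform
random amounts scaled by m and unbalance the MU weights; m = 0 yields
identical fully open apertures (MCSv = 1 exactly).

What passing tests show: the pipeline's operations implement their stated
definitions exactly, the optimizer descends, and the metrics agree with
brute-force enumeration. What they do not show: realism of the dose
shapes (no heterogeneity, no MLC dynamics, no divergence), clinical-level
mimicking fidelity, or any cohort-level dosimetric claim — the phantom
cohort statistics demonstrate the *procedure*, not clinical numbers.

## Problem sizes

Unit tests run on 6³–32³ grids with brute-force oracles; the phantom
invariant fuzz uses 100 seeds at 64³/4 mm (same physical anatomy as the
default); the end-to-end optimizer check runs the default 128³/2 mm
phantom with the standard 2-fold decimation. The acceptance script scores
the default phantom and 100 synthetic plans.
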