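# Methods

## Problem and measurement model

The transverse force couple of the shoulder — the subscapularis (Ssc)
anteriorly against the infraspinatus plus teres minor (Isp+TM) posteriorly —
stabilizes the glenohumeral joint, and its imbalance is implicated in
anterior shoulder instability.  `musclesect` quantifies this balance from a
CT examination consisting of an HU-valued volume, a co-registered integer
label map (1 = Ssc, 2 = Isp+TM), and five landmark points, and tracks it
across a four-timepoint perioperative course (preoperative, 1, 6 and 12
months after surgery).

Per exam the pipeline measures *cumulative sectional* muscle models:

* The **Y-view plane** — the radiological oblique-sagittal plane through the
  scapular "Y" — is supplied as three non-collinear world-mm points.  The
  plane's normal is oriented toward a fourth landmark on the medial scapula,
  so "medial" is resolved per exam and never from an axis sign (left and
  right shoulders work identically).
* Parallel planes at 0, 25 and 50 mm medial offsets (perpendicular to the
  Y-view plane) bound the **Y**, **Y+2.5** and **Y+5 cm sections**: the
  regions from each muscle's most lateral extent to the respective plane.
  Sections are cumulative by definition, so the Y section is contained in
  Y+2.5, which is contained in Y+5 (a tested invariant).
* An **inferior cut-off** plane 30 mm below the glenoid-labrum-inferior
  landmark, normal along the declared superior-inferior world axis, excludes
  the inferior muscle margin that shoulder CT protocols do not reliably
  cover.

A voxel belongs to a section iff its label matches, its world-mapped center
lies on the lateral side of (or exactly on) the bounding plane, and on the
superior side of (or exactly on) the cut-off.  Volume is voxel counting
(`count x voxel volume`); CT density is the unweighted arithmetic mean HU
over the sectional mask (no trimming or windowing; an optional HU clamp
exists but defaults off).  Balance per section is summarised by

    VR    = volume(Ssc)  / volume(Isp+TM)
    CT-DR = mean_hu(Ssc) / mean_hu(Isp+TM)

Ratios are computed per exam and then summarised across subjects (mean of
ratios, not ratio of means).  Undefined denominators yield flagged-missing
(NaN) ratios rather than exceptions.

### Numerical behaviour of the voxel-center rule

The center rule is deterministic and converges to the continuum volume as
spacing shrinks, with one caveat: when a cut plane is exactly parallel to a
grid axis, the cut quantizes to the voxel-column grid and the error is O(h)
at generic plane offsets instead of averaging out.  Validation phantoms
therefore tilt the cut plane slightly (`PhantomSpec.y_plane_normal`), which
restores generic behaviour; at 0.5 mm spacing the observed sectional-volume
error is below 0.1% for ellipsoids with semi-axes of 20 mm or more.  Voxel
centers exactly on a plane are kept; this tie rule matters only on
constructed integer lattices and is tested there in exact arithmetic.
Optional 2x sub-voxel supersampling (`section_fraction_map`) refines
partial-volume handling and is off by default.

The inferior cut-off is anchored to the declared superior world axis, so
sectional measurements are exactly invariant under rigid motions that
preserve that axis (tested), but not under arbitrary rotations of the world
frame — a consequence of the axial-coverage rationale for the cut-off, not
of the implementation.

## Longitudinal statistics

The cohort workflow mirrors a serial perioperative study:

* **Serial paired t-tests** (two-sided, pairwise-complete, no imputation,
  no multiple-testing correction, alpha = 0.05): pre vs 1 month, 1 vs 6
  months, 1 vs 12 months, per metric key.
* **Period differences**, later minus earlier: `Dif.pre.1mo`, `Dif.1.12mo`,
  `Dif.pre.12mo` — an early postoperative drop is negative.  When all three
  timepoints exist, `Dif.pre.12mo` is formed as the sum of the other two, so
  the additivity identity holds exactly in floating point as well as
  mathematically.  Pearson correlations relate the periods.
* **Covariate regression**: one OLS multiple regression per outcome
  difference on 12 clinical/demographic covariates.  Coding: sex male=1,
  side right=1, activity high=1, Bankart bone=1, Hill-Sachs
  none/shallow/deep = 0/1/2, load-shift and sulcus ordinal 0-3, age,
  symptom duration and the three range-of-motion measures untransformed.
  Rank-deficient designs are flagged with the aliased terms named;
  coefficients are then minimum-norm and p-values not interpretable.
* **Interobserver agreement**: ICC(2,1), i.e. two-way random effects,
  absolute agreement, single measure.  The point estimate and variance
  components come from the two-way ANOVA mean squares; the 95% CI is the
  standard F-based interval.  The form is a deliberate default (the
  absolute-agreement single-rater question is the clinically relevant one
  for "would a second radiologist obtain the same number").

Degenerate inputs are flagged, not raised: zero-variance difference vectors
give t = 0, p = 1 (all-zero) or infinite t, p = 0 (constant nonzero);
constant correlation inputs return NaN with a degeneracy flag.

## Synthetic phantoms and cohorts

No patient imagery ships with the package; every stage is validated against
synthetic data whose ground truth is analytic.

**Geometry.** Muscles are ellipsoids, because an ellipsoid cut by a plane
has a closed-form slab volume.  Writing the ellipsoid as the linear image of
the unit ball, the volume on the side `n.x <= d` of a plane is

    V = a b c * pi * (2/3 + t - t^3/3),   t = clip(d_c / a_n, -1, 1)

with `d_c` the signed plane distance from the center and `a_n` the support
half-width along the unit normal `n` (for an axis-aligned cut along the
a-axis this reduces to the familiar pi*b*c*[2a/3 +/- x0 ...] slab formula).
The inferior cut-off is placed tangent to (or below) the lowest muscle so
sectional ground truth stays a pure slab volume.  Grids have even shape with
voxel centers at half-spacing offsets from the world origin, so a plane
through the origin never coincides with a center layer.  HU values are drawn
per voxel from each region's normal distribution; where ellipsoids overlap,
Isp+TM takes precedence deterministically.  Identical spec + seed gives
bit-identical phantoms.

**Trajectories.** Per subject, a drop fraction delta ~ N(0.11, 0.06^2)
(clipped to [0, 0.5]) takes each preoperative volume V to V(1 - delta) at 1
month; recovery returns 0.95*delta of baseline by 6 months and 0.8*delta by
12 months (each plus small noise), echoing the reported course of an early
postoperative drop with near-complete mid-term recovery and a slight
residual deficit at one year.  CT density follows the same mechanism with a
smaller drop (mean 0.06) and essentially full recovery.  Because the
12-month recovery amount grows with the drop, Dif.pre.1mo and Dif.1.12mo are
negatively correlated by construction — the qualitative signature the
statistics must detect.  Optional linear covariate effects (cm^3 per coded
unit) are added to postoperative volumes for regression-recovery tests, and
multiplicative observation noise (default 4%) is applied per observation.
Baseline distributions default to magnitudes typical of adult shoulder CT
(e.g. Y+5 volumes near 110/96 cm^3, densities near 59-65 HU).

The image-level simulator emits one phantom exam per subject x timepoint:
per-subject anatomy scaled by a random overall size, per-timepoint ellipsoid
axes scaled so the full-muscle volume follows the subject's course, and HU
means following the density course.  Postoperative volume is capped at
1.25x baseline so one fixed per-subject cut-off (tangent to that envelope)
stays valid for all timepoints.  Landmarks are identical across a subject's
timepoints.  Default grids use 1.5 x 1.5 x 2 mm voxels on a 15 x 15 x 9 cm
field of view — 2 mm slices matching common shoulder protocols, with the
cohort kept at 24 subjects x 4 timepoints so the full
simulate -> measure -> cohort loop runs in seconds per seed.

**Raters.** Two-rater matrices are latent truth plus i.i.d. cell noise
(optional fixed rater bias), giving expected ICC(2,1) =
var(truth)/(var(truth)+sigma_e^2) for closed-form recovery checks.

**What the phantoms do not emulate**: scapular anatomy, segmentation errors
along real muscle boundaries, CT noise texture, beam hardening, metal
artifact, patient motion, or between-muscle HU gradients.  Passing tests
demonstrate that the geometry, measurement and statistics are correct on
their own terms — not that segmentation-dependent results on patient data
would be unbiased.

## Validation surface

The test suite asserts, among others: analytic recovery for spheres and
random ellipsoid slabs (<=1% at 0.5 mm, error shrinking from 1 mm to 0.25
mm); bit-exact agreement between the vectorized section masks and an
exhaustive per-voxel predicate loop on 64^3 exams; section nesting and
ratio reciprocity over 100 random phantoms; agreement of paired-t, Pearson
and OLS outputs with from-scratch formula evaluation to 1e-10; type-I error
of the paired test within [3%, 7%] under a null simulation (200 replicates
of n=24, p-values pooled over the 12 metric keys); ICC recovery within
[0.88, 0.92] for a 9:1 variance ratio at n=1000; regression-coefficient
recovery within 3 SE at n=500; and the end-to-end drop-and-recover
signature (negative period correlation for every volume metric across 20
simulation seeds, exact difference additivity, significant pre-vs-1-month
drops).  `scripts/acceptance.py` recomputes all of these from scratch and
writes the measured numbers as JSON.

## Known limitations

* Masks are voxel-lattice based; no mesh clipping, so very coarse grids
  (>4 mm) carry percent-level volume error.
* The section definition assumes the label map and CT share one lattice;
  resampled inputs are rejected rather than interpolated.
* The cohort statistics implement exactly the serial-paired /
  period-difference / per-outcome-OLS / ICC workflow; mixed-effects or
  longitudinal models are out of scope.
* Covariate regression with 12 predictors on small cohorts (n near 24) is
  reported as the workflow defines it, but such fits are close to
  saturation; the rank-deficiency flag fires when the design degenerates.
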