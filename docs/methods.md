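# Methods

## Scope and model

`sagspine` analyzes the sagittal alignment of the lumbar spine and
pelvis from 2-D landmark coordinates digitized on standing lateral
radiographs, and asks how well those alignment variables separate
normal controls from patients with acute low back pain (ALBP).  The
pipeline has four stages: a landmark data model, a geometric
measurement layer, an elliptical model of the lordosis, and a
two-group statistical battery.  Because no public landmark data exist
for this setting, a calibrated synthetic generator reproduces the
study conditions end to end.

### Coordinate conventions

x is anterior-positive, y superior-positive, units mm, origin
arbitrary.  Relative (bone-to-bone) angles are invariant to the frame;
gravity-referenced angles (SBA, PT-S1, pelvic tilt) assume y is the
plumb vertical of the upright film.  Lordosis angles (ARA, Cobb) are
negative by convention (extension); SBA, PT-S1 and sacral tilt are
reported as positive magnitudes.

### Landmarks

Eighteen named points per subject: the 13 posterior vertebral body
corners from the posterior-inferior corner of T12 to the
posterior-inferior corner of S1, the anterior-inferior corner of T12,
the anterior-superior corner of S1, the superior aspect of both
femoral heads, and the pubic symphysis.  A set missing any of the 18
is parsed but flagged incomplete; each measurement fails (returns NaN
in `measure_all`) only if a landmark it actually needs is absent.  The
pubic symphysis feeds no angle and is carried for completeness.

### Angle constructions

* **Posterior tangent**: the line through the two posterior body
  corners of a level, oriented cranially.  T12 has no digitized
  posterior-superior corner, so its tangent is constructed as the
  perpendicular to the T12 inferior endplate through the
  posterior-inferior corner — exact for a rectangular body outline.
  This is a design choice forced by the 18-point scheme; the package
  documents it rather than hiding it.
* **ARA (absolute rotation angle)**: difference of the signed
  angle-to-vertical of two posterior tangents (cranial minus caudal);
  ARA L1-L5 and ARA T12-S1 are the two global lordosis measures.
* **Cobb T12-S1**: signed angle between the T12 inferior and S1
  superior endplate lines.  On any noise-free configuration
  |Cobb| = SBA + T12 endplate tilt (the additivity identity used to
  calibrate the generator).
* **SBA / sacral slope**: S1 superior endplate to the horizontal.
* **PT-S1 / sacral tilt**: S1 posterior tangent to the vertical.
* **API (pelvic incidence, Legaye)**: angle at the S1 endplate
  midpoint between the caudal endplate perpendicular and the segment
  to the hip axis (midpoint of the femoral heads).  Satisfies
  PI = PT + SS exactly on noise-free pelves; the property suite
  asserts the residual below 1e-9 degrees on 1,000 random pelves.
* **PTPIA**: angle between the pelvic radius line (hip axis to the
  posterior-superior S1 corner) and the S1 posterior tangent.  The
  exact decomposition is PTPIA = PT-S1 + signed PR lean
  (posterior-positive); with the standard anatomy (hip axis anterior)
  the signed lean is the positive magnitude.  The PR anchor is the
  posterior-superior S1 corner; the alternative (mid posterior S1
  body) is a known ambiguity of the construction and is not
  implemented.
* **API − lordosis variables**: the lordosis magnitude subtracted from
  API, computed as API + signed lordosis (e.g. 56.8 − 76.3 = −19.5).

### Elliptical lordosis model

The 13 posterior corners are modeled as an arc of an ellipse; the
summary statistic is the ratio b/a of the semi-axes.  Axis labeling
follows the arc geometry: the lordotic arc terminates caudally at (or
near) a vertex of the ellipse, and the axis owning that vertex is
labeled "b", the other "a" (ties broken by taking "a" as the axis most
parallel to the T12-S1 chord).  For typical flat arcs this makes "a"
the craniocaudal axis and "b" the sagittal bulge, and it permits
b/a > 1 when the bulge exceeds the craniocaudal half-span, as observed
clinically (ratios up to 1.5).

Fitting minimizes the summed squared orthogonal distances over center,
semi-axes and rotation.  The default method seeds with the direct
algebraic conic fit (ellipse-specific least squares) and polishes by
jointly optimizing the five ellipse parameters and the 13 projection
angles with a trust-region least-squares solver.  The polish is
deliberately local: axis lengths are bounded within a factor of 4 of
the seed and the center within two data spans, because unbounded
orthogonal-distance fitting of short noisy arcs is ill-posed (the
ellipse inflates toward a parabola while the residual keeps
improving).  If the free fit still leaves the admissible ratio range
(default 0.02–1.6), the fit is retried once with the caudal point
pinned to the b-axis vertex — a constrained, well-posed variant also
available directly via `FitOptions(pin_caudal_vertex=True)`.  A
`grid_refine` method (fixed lattice of 12 starting rotations with
axis-aligned algebraic seeds) is retained as an independent
cross-check; both methods agree to 1e-6 on exact arcs.

Numerical notes: collinearity is detected from the singular-value
ratio of the centered points (threshold 1e-8) and raises a dedicated
error; convergence tolerance is 1e-9 relative; everything is
deterministic — no random restarts.

Recovery accuracy on noise-free 13-point arcs spanning 60–110 degrees
is better than 1e-3 in b/a across ratios 0.1–1.5 (in practice machine
precision); shorter arcs degrade gracefully but are not asserted.

## Synthetic cohorts

The generator inverts the geometry: choose target angles, build a
landmark set realizing them exactly, then add digitization noise.
Primary generative parameters are the sacral base angle, the T12
endplate tilt, the S1 posterior-tangent lean (sacral tilt), the pelvic
incidence, and the arc shape (b/a, extent); the lordosis angles are
emergent through the exact identities

    Cobb T12-S1 = -(SBA + t12_tilt)
    ARA  T12-S1 = -(t12_tilt + sacral_tilt)
    PT          =  API - SBA.

These four relations mean the seven published angle means cannot be
set independently — and indeed the published normal means are mutually
consistent with them (e.g. 65.4 = 39.4 + 26.0 and 76.3 = 26.0 + 50.3),
which is what makes this parameterization faithful.

Defaults (units mm/deg): b/a 0.389, arc extent 85, SBA 39.4, T12 tilt
26.0, sacral tilt = SBA + 10.9 (the S1 body wedge implied by the
normal-group means) unless set explicitly, pelvic incidence 56.8,
pelvic radius 110, T12-S1 chord 210, body depth 35, noise SD 0.7 mm
per coordinate.  The posterior corners are spaced along the arc by
curve length in a disc-gap/vertebral-wall pattern of 8 mm : 30 mm
(published lumbar posterior disc and body heights); spacing by
parameter angle would compress the cranial walls of a flat ellipse to
~11 mm and make their tangents unrealistically noise-sensitive.
Femoral heads sit ±4 mm about the hip axis and the pubic symphysis is
a fixed decorative offset.

Cohorts draw the generative variables (SBA, signed Cobb, PT-S1, API,
b/a) from per-group Gaussians, optionally correlated through a
Gaussian copula.  The bundled preset encodes the published group
means/SDs and a Pearson correlation matrix back-converted from the
published Spearman matrix via 2·sin(pi·rho_s/6) and projected to the
nearest positive semi-definite correlation matrix (the unpublished
PT-S1/Cobb cell is interpolated as −0.60 normal / −0.30 ALBP from the
adjacent SBA row).  Draws that are geometrically unconstructible
(derived T12 tilt non-positive, hip axis above the endplate, ratio
outside the fittable range) are rejected and redrawn; a rejection rate
above 50% is a specification error.  Clipping draws to the published
observed min/max ranges is available (`bounds=`/`clip_to_ranges`) but
off by default, because range clipping shifts the group means (for the
ALBP Cobb row by ~+0.6 deg) and the generator's first duty is to
reproduce the specified means.  Everything is reproducible bit-for-bit
from the spec seed.

`summary_cohort` skips landmark construction and draws measurement
vectors directly from the group Gaussians — the binormal approximation
used for large-n ROC experiments.

### What the generator does and does not emulate

It reproduces: the group means/SDs and approximate correlation
structure of the published cohorts, the exact geometric identities
among the angles, and digitization noise whose derived per-angle SEM
(1.6–2.8 deg at 0.7 mm noise) matches the ~2 deg reliability reported
for these radiographic measures.  It does not emulate: biofidelic
vertebral shapes, pathology (osteophytes, degeneration), positioning
error, the non-normality of the real distributions, or the exact
sample-level values of the original radiographs.  Consequently,
passing tests demonstrate correctness of the measurement and
statistical machinery under the study's distributional conditions,
not reproduction of the original per-subject data; published
quantities that depend on the raw data (individual correlation
coefficients, most ROC cutoffs and their sensitivities) are checked
for direction and internal consistency only.

## Statistics

* **Descriptives/t-test**: per-group mean/SD/max/min/n and a two-sided
  independent-samples t-test (Student pooled-variance by default,
  Welch optional).  Zero variance in both groups flags the t as
  undefined.
* **Normality**: Shapiro-Wilk and Lilliefors (Kolmogorov-Smirnov)
  flags, reported only — they never switch methods automatically.
* **Spearman**: tie-corrected average ranks, Pearson correlation of
  the ranks, p by the t-approximation; constant columns yield NaN.
* **Cohen's d**: pooled-SD standardized mean difference.  On the
  published SBA summaries (n = 50/group) d = 0.617; on the Cobb
  magnitudes d = 0.471.
* **Sample size**: smallest n per group with two-sample noncentral-t
  power ≥ target (df = 2n−2, noncentrality d·sqrt(n/2)), found by
  doubling + bisection on the monotone power curve and verified
  minimal by exhaustive scan in the tests.  For d = 0.471 this gives
  72 per group (144 total).  The published SBA figure of 45 per group
  is not reproduced by the noncentral-t (or normal-approximation)
  calculation, which gives 43; it is treated as a known discrepancy,
  not a target.
* **ROC**: empirical curve over all distinct observed thresholds with
  the fixed orientation "value ≥ cutoff predicts ALBP", never
  auto-flipped, so anti-discriminating variables legitimately report
  AUC < 0.5.  The trapezoidal AUC equals Mann-Whitney U/(n0·n1) with
  half-credit for ties (asserted against exhaustive pair counting).
  The optimal cutoff maximizes Youden's J; among ties the largest
  cutoff is reported.  The reported K-S metric is the oriented ECDF
  separation max(F_control − F_patient), which equals the maximal J on
  every input and coincides with the classical two-sample K-S
  statistic whenever the patient group is stochastically larger.
* **Model objects**: `CohortComparison(df).fit()` bundles the battery
  into a results object with `summary()`, `roc_table()` and
  `to_dict()`; `LordosisEllipse(points).fit()` does the same for the
  ellipse.

## Problem sizes and tolerances used in the checks

Effect sizes and sample size are exact computations on the published
summaries (tolerances 0.001 and exact integer).  The SBA ROC AUC is
estimated from 10^6 draws per group (tolerance ±0.01 against the
published 0.665; the closed-form binormal value is 0.669).  Generator
fidelity uses 500 noise-free subjects per run (tolerance ±0.5 deg on
the group mean; sampling SE ≈ 0.45 deg).  The identity suites run
1,000 random pelves at 1e-9 deg.  The noise-realism check uses 200
re-digitizations of one subject at 0.7 mm and asserts each angle SEM
inside 1–3 deg, a band rather than a point, because the cited ~2 deg
is itself a rounded reliability summary.

## Known limitations

* The T12 posterior tangent is a perpendicular construction, not a
  digitized posterior wall; on non-rectangular bodies it differs from
  the true tangent by the body's posterior wedge angle.
* The ellipse fit's local-polish formulation trades a small bias
  toward the algebraic seed for well-posedness on noisy arcs.
* The Gaussian cohort model cannot reproduce published quantities that
  depend on the real data's non-normality (e.g. the published SBA
  cutoff 41.2 with sensitivity 0.70/specificity 0.62).
* Segmental (per-disc) angles, coronal-plane measures and disc heights
  are out of scope.
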