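# Methods

## Model and assumptions

The pipeline treats the acetabular opening as a plane: the face normal
fitted to the labelled rim points is the acetabular axis.  This is the
standard rim-plane definition; no sphere or ellipsoid is fitted to the
lunate surface, and any systematic bias between the rim-plane normal
and a "true" socket axis is outside the model.  The arc left unlabelled
over the transverse acetabular ligament does not bias a noise-free fit
(any ≥3 coplanar points determine the plane) and its angular extent is
recorded per hip (`arc_coverage_deg`) rather than corrected for.

Reference planes are patient-specific, built from bony landmarks rather
than the scanner axes, so every reported angle is invariant under rigid
motion of the whole coordinate set (verified to 1e-9° in the tests).
The coronal reference is the anterior pelvic plane; this assumes the
supine APP is an acceptable surrogate for the true coronal plane.  No
functional (standing) tilt correction and no spinopelvic adjustment is
applied — both are out of scope.

## Plane fitting

All plane fits are total least squares: the normal is the smallest
principal direction of the centered point cloud (SVD), the plane passes
through the centroid, and the reported residual is the RMS of
*orthogonal* distances in mm.  Degeneracy (collinear or coincident
points) is detected as a second singular value below 1e-8 of the
largest and raises an error rather than returning an arbitrary plane.
The tests pin this fit against an independent brute-force search over
normal directions (Fibonacci hemisphere grid + Nelder-Mead polish) to
1e-3 mm RMS.

## Reference-frame construction and sign conventions

* Coronal (APP): TLS plane through the 4 ASIS/pubic points; normal
  points **anteriorly** (away from the sacral-crest centroid).
* Sagittal: TLS plane through {ASIS midpoint} ∪ sacral points; normal
  points toward the patient's **right** (right ASIS on the positive
  side).
* Transverse: *constructed*, not fitted — normal is
  n̂\_coronal × n̂\_sagittal through the ASIS-midpoint origin, oriented
  cranially.  This makes the sagittal-transverse angle exactly 90° for
  every input and the coronal-transverse angle 90° to numerical
  precision.  A "literal" mode that crosses the left→right ASIS vector
  with the sagittal normal instead is exposed for comparison
  (`build_transverse(..., mode="literal")`, CLI `--transverse literal`);
  because the inter-ASIS vector is nearly parallel to the sagittal
  normal, that cross product is near-degenerate and fails loudly on
  clean geometry — which is why it is not the default.
* Longitudinal axis: coronal ∩ sagittal intersection direction,
  oriented cranially.  The cranial resolver is the ASIS-midpoint minus
  pubic-midpoint direction — the pubic tubercles are unambiguously
  caudal to the ASIS in any pelvis, whereas sacral-crest points can
  straddle the ASIS level.
* Transverse axis: coronal ∩ transverse intersection, oriented from the
  left ASIS toward the right.
* The transverse plane's offset (its D coefficient) is inert — every
  downstream angle uses only normals — but is fixed through the origin
  for definiteness.

The per-case perpendicularity audit reports the three pairwise
*oriented-normal* angles in [0°, 180°] without folding to the acute
value: 88° and 92° are different audit outcomes, and folding would
erase the distinction.

## Angle definitions and reporting conventions

With the oriented axis decomposed as (ℓ, a, c) = components along the
(lateral-for-that-side, anterior, cranial) frame axes:

* **AI** — angle(axis, longitudinal axis).  The raw oriented angle for
  an infero-laterally pointing axis is ~140°; by default inclinations
  are folded to min(θ, 180°−θ) so canonical anatomy reads on the
  clinical 30–60° scale.  The raw angle is kept (`ai_raw`); folding can
  be disabled (`fold=False`, CLI `--no-fold`).
* **AA** — axis projected into the transverse plane, measured from the
  transverse axis, signed positive anterior.
* **OI** — line-plane angle between the axis and the sagittal plane,
  signed positive toward the hip's own lateral side.
* **OA** — axis projected into the sagittal plane, measured from the
  longitudinal axis, folded, signed positive anterior.
* **RI** — axis projected into the coronal plane, measured from the
  longitudinal axis, folded (unsigned).
* **RA** — line-plane angle between the axis and the coronal plane,
  signed positive anterior.

Anteversion sign: negative values mean retroversion and are reported as
such, never clamped.  When the axis lies within 1e-8 of a reference
normal the corresponding projection has no direction; the angle is
reported as NaN with a named flag (`AA`, `OA` or `RI`), never as 0.
The axis-orientation step itself errors when the rim normal has no
lateral component (sign genuinely ambiguous).

The closed forms cos AI = |c| (folded), tan AA = a/ℓ, sin OI = ℓ,
tan OA = a/|c| (signed by a), tan RI = |ℓ|/|c|, sin RA = a were derived
by hand from this decomposition and serve as an independent test oracle
(1,000 random axes, 1e-9° agreement); the pipeline itself always
computes via projections and the inverse-cosine formula.

## Conversion-formula residuals

Cross-system conversions are evaluated exactly as commonly printed:

    r1 = OA − tan⁻¹(sin RI · cos RA)
    r2 = AA − tan⁻¹(cos OI · cos OA)
    r3 = RA − sin⁻¹(tan OI · cos OA)

These expressions are **not** self-consistent identities — r2 evaluates
to −45° even on the all-zero angle set, and r3's arcsine argument can
leave [−1, 1] (flagged as undefined) — and the package reproduces them
verbatim because their failure on exact geometry is itself the finding.
For comparison, a `textbook=True` flag also reports residuals against
the self-consistent identities implied by the axis decomposition,

    OA = tan⁻¹(tan RA / cos RI)
    AA = tan⁻¹(tan RA / sin RI)
    RA = tan⁻¹(tan OA · cos RI)

which vanish (≤1e-9°) on exact angle sets; the derivation is one line
each from ℓ² + a² + c² = 1.

## Landmark protocol and rater agreement

Validation enforces the labelling protocol: ≥30 rim points per hip, ≥3
sacral-crest points, non-coincident ASIS (>1 mm) and pubic landmarks,
and a warning when rim spacing is grossly non-uniform (coefficient of
variation of nearest-neighbour spacing > 0.6 — an evenly spaced rim
stays below ~0.5 even under 2 mm jitter, clusters of duplicates exceed
it).  Strict mode turns violations into errors.

Two-rater agreement compares named landmarks role-by-role and rim
clouds — which carry no stable point identity between raters — by the
symmetric Hausdorff distance (worst nearest-neighbour mismatch in
either direction; the symmetric form keeps agreement(a, b) ≡
agreement(b, a)).  A case passes when every distance is below the 2 mm
tolerance.

## Synthetic-pelvis generator

Canonical frame: x = patient left→right, y = posterior→anterior,
z = caudal→cranial.  Landmarks: ASIS at (±120, 0, 0) mm (width 240 mm),
pubic tubercles at (±36, 0, −90) (coplanar with the ASIS, so the
canonical APP is exactly y = 0), three sacral points on x = 0 about
90–102 mm posterior, rim circles of radius 25 mm (30 points, 60°
ligament gap) centered ±80 mm laterally.  Dimensions are plausibility
values for an adult pelvis, chosen for test realism.  The rim-plane
normal realizes the requested anatomical (AI, AA) truth exactly;
per-side truths can differ (used by the cohort generator).

Noise model: independent isotropic Gaussian jitter per landmark
(`landmark_jitter_sd`), plus optional out-of-plane rim displacement
along the true axis (`rim_out_of_plane_sd`, modelling the non-planar
rim).  The rigid pose (Euler tilt/rotation + translation) is applied
after noise; ground truth is stored in posed coordinates.  All
randomness flows from one explicit seeded generator — no global RNG
state.

Cohort defaults: per-hip anatomical truths AI ~ N(37.48°, 11.07°²),
AA ~ N(18.12°, 7.59°²) truncated to AI ∈ [10°, 80°], AA ∈ [−20°, 50°]
for geometric validity; 57.14% male; age bins <30 / 30s / 40s / ≥50
with probabilities 0.367/0.163/0.388/0.082 and ages uniform within the
18–56-year span.  The single-pelvis default truth is AI = 40°,
AA = 15°, the lower bounds of the accepted clinical target ranges.

What the generator does *not* emulate: real bone-surface geometry,
segmentation/reconstruction error structure (jitter is isotropic and
independent, real labelling error is not), non-planar rim shape beyond
symmetric noise, and anatomical covariance between landmarks.  Passing
recovery tests therefore demonstrates correctness of the geometry and
the noise response of the estimators — not clinical accuracy on real
CT reconstructions.

## Cohort statistics

Sampling unit is the hip; both hips of a case enter independently and
within-patient correlation between sides is ignored — a known
statistical limitation (no mixed-effects modelling).  Normality is
screened per measurement with the KS statistic against a normal with
sample-estimated mean/SD and Lilliefors-calibrated p-values (the naive
KS p with plugged-in parameters has type-I error near zero; the
calibrated test sits at the nominal 0.05, verified by simulation).
Measurements failing the screen are Blom-transformed,
Φ⁻¹((rank − 3/8)/(n + 1/4)), and rescaled to the original mean/SD so
tabulated values stay in degrees.

Plane-pair angles are compared with 90° by a one-sample t test (a
"two-sample" test against a constant reduces to this; zero-variance
input is an error, not a p-value).  Sex subgroups use a pooled
two-sample t test.  Age-group association for a continuous angle is
underdetermined as a chi-square problem; it is implemented as the
age-bin × (above/below cohort median) contingency chi-square, with a
one-way ANOVA across bins reported alongside so both readings are
available.  The three-system comparison is a one-way ANOVA with Fisher
LSD pairwise contrasts — t on the pooled within-group mean square with
N−k df, unadjusted for multiplicity by definition; an optional
Bonferroni column serves modern practice.

## Numerical choices

Degeneracy threshold 1e-8 on relevant norms throughout (landmarks are
mm-scale with ~0.1 mm precision).  Cosine arguments are clamped to
[−1, 1] before arccos, so near-parallel directions cannot produce NaN.
Angles are degrees at every module boundary; radians exist only inside
trig calls.  Plane normals are unit to 1e-12 by construction.

## Problem sizes used in the validation suite

Closed-form oracle agreement: 1,000 random axes.  Rigid-motion
invariance: 100 random transforms.  Noise recovery: 200 replicates at
1 mm jitter (median |error| < 1.5° per angle).  Plane-fit oracle: 50
random 10-point clouds.  Statistical calibration: 1,000 null
replicates at n = 98 for the normality screen and the vs-90° t test;
100 replicates of the three-group ANOVA pattern at n = 98 per group.

## Known limitations

* The rim-plane axis ignores any systematic rim-vs-socket bias.
* Supine APP ≈ coronal is assumed; no standing/functional correction.
* Rater-agreement nearest-neighbour matching is a convention — rim
  points have no identity across raters, so per-point correspondence is
  undefined in principle.
* Cohort tests treat hips as independent.
* The synthetic generator's noise is idealized (see above), so
  simulation-based calibration statements transfer to real data only to
  the extent real labelling error resembles isotropic jitter.
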