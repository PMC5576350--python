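# acetorient

Measurement of acetabular cup orientation — inclination and anteversion
in the **anatomical**, **operative** and **radiographic** systems — from
3-D bony-landmark coordinates exported from a reconstructed pelvis.

## The problem

The orientation of the acetabulum (and of a cup prosthesis in total hip
arthroplasty) is described by an inclination/anteversion pair, but three
incompatible definition systems are in clinical use: anatomical (axis
against the body planes), operative (axis against the sagittal
plane, as seen by the surgeon with the patient in lateral position) and
radiographic (the projection seen on an AP film).  The same socket
yields three different numbers, and published conversion formulas
between the systems do not, in general, hold.  This package measures all
six angles from the same landmark set — so the divergence between
systems can be quantified per hip — using patient-specific reference
planes that remove scanner-pose bias.

## Method

Per case, from landmark coordinates (mm, arbitrary scanner frame):

1. **Reference frame.** The coronal reference is the anterior pelvic
   plane (APP): the total-least-squares plane through the bilateral
   anterior superior iliac spines (ASIS) and pubic tubercles.  The
   sagittal plane is fitted through the ASIS midpoint and ≥3
   sacral-crest points.  The transverse plane's normal is
   n̂<sub>cor</sub> × n̂<sub>sag</sub>, exactly perpendicular to the
   sagittal plane by construction.  The longitudinal (cranio-caudal) and
   transverse (left-right) body axes are the plane intersection lines.
2. **Acetabular axis.** Each hip's ≥30 rim points are fitted with a
   total-least-squares plane (normal = smallest principal direction of
   the centered cloud); the oriented normal, pointing out of the socket,
   is the acetabular axis **n̂**.
3. **Angles.** With axis components (ℓ, a, c) along the (lateral,
   anterior, cranial) frame axes, the pipeline computes geometrically
   (projections + θ = cos⁻¹(u·v/|u||v|)) the six angles whose closed
   forms are

   | system | inclination | anteversion |
   |---|---|---|
   | anatomical | cos AI = −c | tan AA = a/ℓ |
   | operative | sin OI = ℓ | tan OA = a/(−c) |
   | radiographic | tan RI = ℓ/(−c) | sin RA = a |

   Inclinations are folded to the acute value so canonical anatomy lands
   on the clinical 30–60° scale; anteversion is signed (negative =
   retroversion).
4. **Conversion residuals.** Per hip, the residuals of the printed
   cross-system conversion formulas, e.g. r₁ = OA − tan⁻¹(sin RI·cos RA),
   which are generically non-zero even for exact geometry.
5. **Cohort statistics.** Lilliefors (KS) normality screening with Blom
   rank-normalization fallback, one-sample t tests of the plane-pair
   angles against 90°, sex/age-bin subgroup comparisons, and one-way
   ANOVA with Fisher LSD contrasts across the three systems.

A seeded synthetic-pelvis generator provides landmark sets with known
ground-truth axes, configurable rim geometry and noise, rigid pose, and
a second-rater perturbation for the 2-mm agreement protocol.

## Worked example

```sh
acetorient simulate --out sim --seed 42 --n-cases 3   # synthetic landmarks + truth
acetorient measure --in sim --out meas                # six angles per hip
```

`meas/measurements.csv` (noise-free generator defaults, so the measured
angles reproduce `sim/ground_truth.csv` exactly):

```
case_id  side    AI    AA    OI    OA    RI    RA
case000  left 40.85 10.23 40.07  8.73 40.40  6.67
case000 right 45.79 25.26 40.41 23.68 42.91 17.81
case001  left 37.29 11.65 36.40  8.74 36.72  7.03
case001 right 47.21 24.02 42.09 23.74 44.62 17.38
case002  left 27.97 20.92 25.98 10.74 26.38  9.64
case002 right 26.87 24.79 24.22 11.99 24.70 10.92
```

Each row is one hip: e.g. case000/right has an anatomical inclination of
45.8° and anatomical anteversion of 25.3°, while the same socket would
read 42.9°/17.8° on an AP radiograph — the between-system divergence the
package exists to expose.  The same pipeline is available in Python:

```python
from acetorient import SyntheticSpec, generate_pelvis, measure_all

lset, truth = generate_pelvis(SyntheticSpec(true_ai=40, true_aa=15))
report = measure_all(lset)
report.hips[0].angles.as_dict()
# {'AI': 40.0, 'AA': 15.0, 'OI': 38.38, 'OA': 12.25, 'RI': 39.03, 'RA': 9.58}
```

`acetorient cohort --in measurements.csv --out out/` summarizes a
measurement table (mean ± SD overall and by sex/age bin, normality
screening, ANOVA + LSD across the three systems).

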