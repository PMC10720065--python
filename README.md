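# mandasym

Quantification of three-dimensional mandibular asymmetry from segmented
CBCT, for craniofacial morphometry: orthodontics and orthognathic-surgery
research where sub-clinical asymmetries (menton deviation < 2 mm) must be
measured rather than eyeballed.

## Method

The measurement follows the mirror-and-register paradigm:

1. **Midsagittal plane** through the Anterior Nasal Spine, Nasion and the
   midpoint of the fronto-zygomatic points.
2. **Mirroring**: the mandible surface (or binary mask) is reflected across
   that plane, `p ↦ p − 2(n·p − d)n`.
3. **Cranial-base registration**: the mirror image is rigidly registered
   back onto the original using only cranial-base/maxillary landmarks
   (Nasion, Basion, ANS, fronto-zygomatic points) with the closed-form
   Kabsch/SVD solution, so positional asymmetries (head pose, glenoid-fossa
   position) are removed and residual differences are morphological.  An
   optional voxel stage refines the pose by maximizing binary-mask Dice in
   a region of interest.
4. **Hemimandibles**: both surfaces are clipped at the midsagittal plane;
   the right hemimandible is the reference.
5. **Distance field**: every reference point is connected to the closest
   point of the mirrored contralateral surface.  With displacement vector
   **v** = (X, Y, Z) and outward reference normal **n**,

   signed distance = sign(**v**·**n**) ‖**v**‖,   absolute = ‖**v**‖,

   positive when the left hemimandible tends to contain the right.
   Values are aggregated by anatomical region — condyle, ramus, corpus —
   delimited by an axial plane through the sigmoid notch and an oblique
   plane through Gonion.
6. **Statistics**: per-class and per-region summary tables, one-sample
   t-tests against 0, one-way ANOVA with Bonferroni pairwise comparisons,
   Levene and Lilliefors-corrected Kolmogorov–Smirnov checks, ICC(2,1)
   reliability, and one-way-ANOVA power via the noncentral F distribution,
   `power = P(F′(k−1, N−k, λ = f²N) > F_crit)`.
7. **Color maps**: surfaces exported (VTP / PLY) with the signed distance
   per vertex on a diverging scale clamped to the clinically relevant
   ±2 mm range (dark blue −2, blue −1, neutral 0, yellow +1, red +2).

Because patient CBCTs cannot be shipped, the package includes a synthetic
mandible generator: an exactly bilaterally symmetric template (implicit
corpus arch + ramus slabs + condylar ellipsoids, extracted by marching
cubes) with analytic landmarks, ground-truth region/side labels, injectable
regional deformations of known magnitude, and cohort sampling over sagittal
(Steiner ANB: class I 2°±2°, II > 4°, III < 0°) and vertical (Ricketts FMA:
brachy < 22°, meso 22–28°, dolicho > 28°) skeletal classes.

## Worked example

Inject a known 2 mm outward dilation of the left condyle and recover it:

```python
import mandasym as M

mesh, landmarks, labels = M.generate_mandible()
spec = M.AsymmetrySpec(region="condyle", side="left",
                       mode="outward_dilation", magnitude=2.0)
field = M.measure_subject(M.apply_asymmetry(mesh, spec), landmarks)

print(f"points measured:      {field.n_points}")
print(f"mean signed distance: {field.signed.mean():+.3f} mm")
for region, mean in sorted(field.region_mean_signed().items()):
    print(f"  {region:<8s} mean signed: {mean:+.3f} mm")
print(f"power (k=3, N=60, f=0.4): {M.anova_power(3, 60, 0.4):.3f}")
```

prints

```
points measured:      5786
mean signed distance: +0.240 mm
  condyle  mean signed: +1.932 mm
  corpus   mean signed: -0.000 mm
  ramus    mean signed: +0.000 mm
power (k=3, N=60, f=0.4): 0.776
```

The condyle-region mean recovers the injected +2 mm within a few percent
(the deficit is the closest-point transition band at the region boundary);
the untouched regions stay at zero; the positive sign encodes "left
contains right".

## Command line

```sh
asym synth --preset demo --seed 1 --out demo/      # synthetic cohort on disk
asym subject --config subject.yaml                 # one subject -> field CSV, color maps, summary JSON
asym cohort  --config cohort.yaml                  # cohort -> class/region tables, test report
```

Configs are flat YAML files; see `mandasym.cli` for the accepted keys.

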