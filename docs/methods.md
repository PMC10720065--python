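# Methods

## Coordinate convention

All geometry lives in a right-handed RAS frame in millimetres: +x patient
right, +y anterior, +z superior.  The midsagittal normal is oriented toward
the patient's **left**, so a displacement along +normal means the left-side
surface lies farther out than the right — this single convention makes
"signed distance > 0 ⇔ left hemimandible contains the right" hold
everywhere without per-case sign fixes.

## The measurement model

Asymmetry is defined as the difference between a hemimandible and the
mirror image of the contralateral one, after the mirror has been rigidly
registered to the original on cranial-base references only (Nasion, Basion,
ANS, fronto-zygomatic points — never mandibular points).  Registering on
the cranial base removes positional asymmetry (head pose, fossa position);
what remains is morphological.  The registration is the closed-form
orthogonal-Procrustes/Kabsch solution with det(R) = +1 enforced; the
residual RMSD is attached to the transform.  A voxel refinement stage is
available for mask inputs: deterministic coordinate descent over the six
rigid parameters maximizing binary-mask Dice within a region of interest,
with a fixed step schedule (2, 1, 0.5, 0.25 voxels / degrees) and sweep
cap.  Dice on binary masks stands in for grey-value similarity because the
pipeline's inputs are segmentation products, not intensities; by
construction the refined pose never scores below its initialization.

Point correspondence is **closest point on the registered target surface**
for every reference vertex.  This replaces spherical-harmonic (SPHARM-PDM)
correspondence: on pre-registered, nearly congruent surfaces the closest
point approximates the homologous point, and it is exact, deterministic and
dependency-free.  The known cost is a transition band at deformation
boundaries where closest-point distances undershoot the true displacement
(see *Validation* below).  The closest-point query is exact: candidate
triangles from a k-d tree over triangle centroids, widened by the largest
triangle circumradius so the true minimizer is always among the candidates,
then vectorized point–triangle projection; a brute-force all-pairs oracle
verifies it in the tests.

Signed distance is sign(v·n)·‖v‖ with v the reference→target displacement
and n the outward reference normal.  The containment wording ("left tends
to contain the right") has a unique local formalization: the corresponding
surface lies outside the reference exactly when v points along the outward
normal.  Absolute distance is ‖v‖.  With the left hemimandible as
reference the reported sign flips, matching the reference-swap behaviour
expected of the measurement.

## Region partition

Condyle, ramus and corpus are separated by two landmark-anchored planes per
side: the axial plane (natural-head-position frame) through the sigmoid
notch (condyle above), and an oblique plane through Gonion whose normal
bisects the gonial angle, (ŷ − ẑ)/√2 (corpus anterior-inferior of it,
ramus the remainder).  The classical delimitation is a 2-D panoramic
construction; this is its 3-D adaptation, chosen so that both the labeler
and the generator's ground truth are defined by the same planes — the
agreement test (≥ 95 %) therefore validates that landmarks placed on the
template actually reproduce the analytic partition, not two unrelated
definitions.

## Natural-head-position frame and cephalometrics

The axial plane is the occlusal plane, least-squares fit through the two
maxillary first-molar mesiobuccal cusps and the incisal midpoint (the fit
is used because only the plane, not the fitting rule, is standard); +z is
its normal toward Nasion, +x the left→right fronto-zygomatic direction
projected into it, origin the mid fronto-zygomatic point.  ANB is the
signed angle at Nasion between the rays to A- and B-point in the sagittal
projection of this frame (positive when A is anterior); FMA is the
dihedral angle between the Frankfort plane (Porion/Orbitale, least-squares)
and the mandibular plane (Gonion ×2, Menton), clamped to [0°, 90°].  Class
boundaries follow the printed thresholds strictly: ANB exactly 4° is class
I (class II is strictly > 4°), ANB in [0°, 4°] is class I, below 0° class
III; FMA 22° and 28° are mesocephalic (closed band).  Both angles are
invariant to global rigid motion because the frame is rebuilt from the
landmarks.

## Synthetic data: what it emulates and what it does not

The template is the zero level set of a union of implicit primitives — a
quarter-ellipse corpus arch swept with an elliptical cross-section, two
rounded ramus slabs, and two elongated condylar ellipsoids whose lower half
forms the neck and overlaps the ramus below the sigmoid notch (chosen so
the condyle/ramus junction crease is short).  Every primitive depends on x
only through |x| and the marching-cubes grid is symmetric about x = 0, so
the template is bilaterally symmetric; duplicate-vertex welding plus
mirror-pair averaging pins the symmetry to machine precision.  Default
dimensions approximate an adult mandible: corpus length 75 mm, ramus
height 50 mm, condyle radius 9 mm, intergonial width 95 mm, symphysis
height 13 mm; the marching-cubes spacing is derived from a surface-area
estimate to hit the requested point budget (default 20 000).

Ground-truth deformations displace exactly the vertices of one
region/side: along outward vertex normals (`outward_dilation`), away from
the midline (`lateral_shift`), or along the superior/anterior axis
(`elongation`); the maximum displacement equals the requested magnitude
exactly.

Skeletal classes are encoded in the landmarks, not the mesh: B-point is
placed on a ray at the target ANB from Nasion, and the Frankfort landmarks
(Porion/Orbitale) are inclined by the target FMA against the horizontal
mandibular plane.  Moving Gonion/Menton instead would detach them from the
mesh and corrupt the region labeler, so the Frankfort inclination carries
the vertical class; anatomically this is a head-tilt proxy, adequate
because the classifier consumes only relative landmark geometry.  Cohorts
sample ANB/FMA uniformly inside each class band (I: 0.5–3.5°, II:
4.5–8°, III: −4 to −0.5°; brachy 16–21°, meso 22.5–27.5°, dolicho
28.5–34°), apply a per-subject asymmetry drawn from a configurable sampler,
and a small random scanner pose (≤ 5°, ≤ 10 mm) so the registration stages
do real work.  The default sampler describes a clinically symmetric cohort
(menton deviation < 2 mm holds by construction): half-normal magnitudes
with 0.6 mm scale, region probabilities 0.45/0.30/0.25
(condyle/ramus/corpus), 55 % left-sided, outward dilation — chosen once to
reflect a cohort with sub-millimetre, condyle-dominant, mildly left-sided
asymmetry.  The default cohort split is 21/20/19 sagittal and 22/19/19
vertical subjects.

Not emulated: CBCT intensities (only binary masks), teeth and restorations,
landmark identification error (landmarks are analytic), inter-subject shape
variability beyond the parameter set, and real biological asymmetry
patterns.  Passing tests therefore demonstrate that the *pipeline* recovers
known ground truth under realistic geometry — not that any clinical
population behaves like the generator.

## Voxelization

A voxel is occupied iff its center lies inside the watertight surface,
computed by column parity: the z-crossings of every projected triangle are
collected per (x, y) grid column and centers between odd/even crossing
pairs are inside.  The grid origin carries a fixed irrational sub-voxel
offset so columns avoid edge-grazing degeneracies; a column that still ends
up with an odd crossing count has its unpaired crossing dropped.  Masks use
the ITK convention (origin = center of voxel (0,0,0)); NRRD I/O goes
through SimpleITK.

## Statistics

Summary rows report mean, sample SD (n−1), min, max, median and a
t-quantile 95 % CI (matching small per-class n).  ANOVA is the classical
between/within decomposition; Bonferroni multiplies pairwise t-test
p-values by the number of pairs (capped at 1).  Normality uses the
Kolmogorov–Smirnov statistic with the Lilliefors correction, since mean and
SD are estimated from the sample and the raw KS p-value would be
anticonservative.  Reliability is ICC(2,1) — two-way random effects,
absolute agreement, single measure — computed from the mean squares; at
least 3 subjects and 2 raters with no missing cells are required.  Power
uses the noncentral F distribution with λ = f²N.  Pooled per-point
analyses ignore within-subject correlation (points are not independent);
no pointwise p-value maps are produced.

## Numerical choices and edge cases

- Planes normalize their normal on construction; degenerate (collinear or
  coincident) defining points raise a named error.
- Mesh reflection flips face winding so outward normals stay outward;
  reflection of a mask is a nearest-neighbour resample (exact for
  grid-aligned planes), grown to cover the transformed occupancy unless an
  output grid is given.
- Hemimandible clipping keeps the cut open (no cap): capping would inject
  artificial zero-distance area at the symphysis into surface-to-surface
  distances.
- Zero-length displacement vectors get signed distance exactly 0; zero
  normals are an error.
- The neutral color map anchor is grey by default and green optionally,
  since published scales use both; colors are piecewise-linear per channel
  and exact at the anchors; values are clamped to ±2 mm.
- All randomness flows from one seeded generator per entry point;
  identical seeds give bit-identical cohorts.

## Problem sizes

Default test and acceptance runs use the 20 000-point template budget
(~11 500 vertices, ~5 800 reference hemimandible points), cohorts of 6–9
subjects at 5 000–8 000-point budgets for the command-line demos, 10 000
null simulations for type-I calibration and 20 000 Monte-Carlo replicates
for the power cross-check — sizes chosen to characterize the estimators
well while keeping a full run in minutes on one core.

## Known limitations

- Closest-point correspondence undershoots true displacement magnitude in
  a band (~the deformation magnitude wide) around deformation boundaries;
  region means of a 2 mm dilation recover ≈ 1.93 mm on the default
  template.  True homologous correspondence (e.g. spherical-harmonic
  parameterization) would not have this bias.
- The voxel refinement optimizes mask overlap, not grey-value similarity,
  and its coordinate descent can stall on a non-axis-aligned saddle; the
  landmark stage provides the initialization that makes this irrelevant at
  the offsets seen here.
- Region boundaries are planes; real condyle/ramus/corpus transitions are
  not planar.
- The generator's classes differ only in landmarks, so class-wise asymmetry
  distributions are exchangeable by design — suitable for null calibration,
  unsuitable for simulating class-correlated asymmetry without injecting it
  explicitly via the sampler.
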