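# Methods

This note records the scientific model behind `craniage`, the defaults
that matter, and the limits of what the synthetic experiments show.

## The generative age model

Each synthetic subject carries latent variables that age acts on:

* **Dens–atlas gap.** The distance between the anterior dens surface and
  the inner atlas arch surface in the joint's upper third interpolates
  linearly from 3.0 mm at age 17 to 0.5 mm at age 79, plus Gaussian noise
  (SD 0.08 mm), floored at 0.2 mm (a joint narrows but never closes).
* **Exostoses.** Three scored sites (superior arch margin, inferior arch
  margin, dens apex) follow per-site logistic curves in age for the
  `absent → present → marked` transitions. Midpoints 35/42/44 years for
  first appearance and 50/52/54 for clear marking, slope 0.8 years: the
  superior margin turns first (during the 31–39 decade), all sites are
  marked by the mid-fifties. The sharp slopes mirror a scale that is
  defined by decade boundaries; prevalence is monotone in age by
  construction.
* **Arrangement.** The arch/dens surface arrangement takes the modal
  category of the subject's age band (angle-open-upward < 21,
  tendency-to-parallel to 37, linear-arcuate to 40, parallel-rectilinear
  to 60, parallel-arcuate above), with a 1.5% chance of an adjacent
  category.
* **Bone brightness.** One latent brightness pair drives both the clivus
  texture on the scanogram and the bone intensity of the 3D phantom: mean
  140 − 0.9·(age−17) with per-subject scatter SD 20, and texture SD
  40 − 0.52·(age−17) with scatter SD 4. Both slopes are negative —
  progressive rarefaction makes old bone darker and more uniform. The
  mean is deliberately noisier than the SD so that the SD is the stronger
  texture age marker, reproducing the ordering of the morphometric
  feature table (SD ≈ −0.8, mean ≈ −0.5 against age, with the involution
  grade on top at ≈ 0.94).
* **Ages** follow a truncated log-normal: offset 17, shape σ = 0.55,
  upper bound 79, location solved numerically so the truncated mean is
  exactly 39. This gives the documented right skew (median < mean, few
  subjects past 60). Sex is Bernoulli(0.54) for male.

All randomness flows from one `numpy` generator per cohort seed;
identical configuration and seed reproduce the cohort bit-for-bit.

## The involution scale

The 0–6 grader is a decision tree over (gap, exostoses, arrangement),
evaluated from grade 6 downward with first match winning:

| grade | rule | age range |
|---|---|---|
| 6 | gap < 1 mm, all sites marked, parallel arrangement | 71+ |
| 5 | gap < 1.25 mm, all marked, parallel | 60–70 |
| 4 | gap < 1.25 mm, all sites at least present | 50–59 |
| 3 | gap < 2 mm, superior site present | 40–49 |
| 2 | gap ≤ 3 mm, superior site present | 31–39 |
| 1 | gap ≤ 3 mm, no exostoses, tendency-to-parallel | 21–30 |
| 0 | otherwise | 14–20 |

"About 1 mm" is encoded as an explicit 1.25 mm upper band edge, kept as a
named constant. Rules carry only upper gap bounds: with top-down
evaluation this makes grading monotone under gap narrowing for any fixed
exostosis/arrangement state, which a banded variant (lower and upper
bounds per grade) would violate. Because the verbal gap criteria of
adjacent grades overlap, exostosis state and arrangement are the actual
discriminators; conflicting cue combinations the scale never describes
(e.g. wide gap with marked exostoses) fall through to the nearest rule
below — grading is a total function. On the default cohort grade 4 is
rarely assigned: between "all present" and "all marked + parallel" the
generator's transitions are fast, so most joints jump from 3 to 5; this
compression is a property of the scale's own definitions.

## Phantom design

The 3D phantom favours analytic ground truth over realism. The atlas is a
full ring (annulus) in the axial plane — as the real C1 is — and the dens
a capped vertical peg on the ring's axis, so the latent gap equals the
inner ring radius minus the peg radius exactly, in every direction. The
ring's **outer** radius is age-constant (7 mm); involution narrows the
joint from the inside. Two consequences matter downstream: the rendered
surface gap matches the latent gap to within one voxel, and every slice
that crosses the ROI box (half-width matched to the outer radius)
intersects bone, which is what makes slice classification learnable —
mirroring real head CTs, where every ROI slice contains tissue.
Exostoses are small spheres (0.6 mm radius when present, 1.1 mm when
marked) at the three scored sites, placed so the apex bump cannot raise
the annotated dens-apex landmark. Bone voxels take the subject's latent
brightness; background is dim Gaussian noise. Default canvas 96³ at
0.5 mm isotropic spacing (48³ in the desk profile); volumes are 0-based,
boxes half-open, Z cranio-caudal.

The 2D scanogram draws the frontal and sphenoid sinuses as dark ellipses
(per-subject geometry scatter, essentially age-free) and the clivus /
clinoid-plate band as Gaussian texture with the latent brightness pair.
Region masks are returned exactly as drawn — segmentation is an input to
morphometry, not a solved problem here.

## Morphometry conventions

"Dots" are mask pixels; the region "center" is the pixel centroid;
"average size" is the mean radial distance from the centroid; elongation
comes from the eigen-decomposition of the 2×2 second central moment
matrix, reported as √(λ₁/λ₂) with the major-axis direction in degrees
from the image X axis in (−90°, 90°]. Mean/max elongation (features
12/13, 15/16) are taken across 8-connected components, which is the only
reading under which they can differ. Brightness moments are population
(divide-by-n) moments; the statistics layer uses sample (n−1) conventions
— the two are deliberately distinct. Scale-free ratios on a constant
region (CV, skewness, excess) return NaN sentinels rather than raising,
so batch extraction never aborts. Maximum pairwise distance is computed
exactly; above 10⁴ pixels it reduces the candidate set via the convex
hull first (still exact).

## Learning stages

Both networks run on the package's numpy core: valid strided
convolutions, ReLU, global average pooling, one dense output; Adam with
cosine-annealed learning rate (floor 1% of the peak, warm restarts
available but off by default); seeded minibatch shuffling makes runs
bit-reproducible per seed.

**Slice classifier.** One model classifies slices from all three
projections without being told the projection. Full-protocol defaults
(batch 128, resize 128, learning rate 10⁻⁶, 10 epochs) suit a large
pretrained backbone, which is a pluggable option; the desk profile
(resize 32, learning rate 0.01, channels 8→16→32) trains the compact CNN
from scratch. The binary cross-entropy weighs the positive class 3×: the
stage is deliberately recall-heavy, because the downstream aggregation
(mean and SD of positive slice indices) absorbs false positives but
cannot recover missed ROI slices. Held-out recall of the positive class
runs ≈ 0.99 at the desk profile; positive precision ≈ 0.95 on phantoms
(far above real-data conditions, where low positive precision is the very
reason the aggregation step exists). Aggregation uses the population SD
of positive axial indices and rounds box corners to the nearest integer;
±1 SD of a uniform slab covers ≈ 58% of it, hence the Dice ≥ 0.5 Z-overlap
property.

**Age regressor.** Crops are trilinearly resampled to cubes and divided
by the fixed 255 full-scale — not min-max normalized — so absolute bone
brightness survives standardization; it is one of the age cues. Desk
profile: 32³ cubes, channels 8→16→32, learning rate 0.01, 30 epochs,
batch 16. Augmentations are axis-aligned 90° rotations (avoiding
resampling blur), axis mirroring and intensity inversion, all
label-preserving. Target (age) normalization is available and off by
default; on the toy affine benchmark it changes test error by little.
The error metric is RMSE in years, with MAE reported alongside. On 200
phantoms the desk protocol reaches ≈ 7–8 years held-out RMSE. Train RMSE
is not systematically below test RMSE here: training batches are
augmented (inversion in particular makes the brightness cue harder)
while evaluation is not, and both splits sit near the generator's
intrinsic noise floor (~5 years from the brightness scatter alone), so
the usual overfitting gap is not observable at this scale.

## Problem sizes

Desk-scale defaults keep every protocol single-CPU friendly: 48³ phantom
volumes, ROI half-width 13 voxels (matching the 14-voxel outer arch
radius at 0.5 mm spacing), 50 volumes for the classifier protocol, 200
for the regression protocol, 32³ cubes, 10/30 epochs. Full-protocol
values (512×512×Z volumes, ±64 half-widths, 64³ cubes, 150 epochs) are
configuration, not code: every constant lives in a config dataclass.

## What passing tests do and do not show

The phantom carries exactly the age signals the generator writes into it,
with known noise, no anatomical variability beyond parameter scatter, no
pathology, no scanner artifacts, and landmark annotations that are exact
by construction. Passing the synthetic protocols therefore validates the
machinery — grading rules, feature definitions, ROI aggregation
arithmetic, training loops, statistics — and the internal consistency of
the pipeline, not clinical performance. Real-data recall, precision and
error values depend on cohort and scanner properties the phantom does not
model, and the rule-based grader takes geometry measurements as input; it
does not read them from pixels.
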