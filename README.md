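# craniage

Forensic age estimation from CT of the craniovertebral junction, rebuilt as
a reusable, fully tested Python pipeline on synthetic phantoms.

## The problem

Estimating the age of an unidentified person from skeletal imaging is a
routine forensic task. Degenerative transformation (involution) of the
median atlantoaxial (Cruveilhier) joint — the articulation between the
anterior arch of the atlas (C1) and the dens of the axis (C2) — is a strong
age marker in adults: the dens–atlas gap narrows from about 3 mm in the
young joint to under 1 mm past 70, bone exostoses accrue at the arch
margins and the dens apex, and the articular surfaces re-align from an
upward-open angle to full parallelism. Bone-texture statistics of the
clivus and clinoid plate (grey-value mean, SD and higher moments) fall
with age as bone mineral rarefies, while frontal/sphenoid sinus geometry
carries little age signal.

`craniage` implements that workflow end to end:

1. **Synthetic cohort** (`craniage.cohort`) — seeded subjects with
   age-dependent latent joint geometry and bone-brightness parameters,
   emulating a 223-subject adult cohort (ages 17–79, right-skewed around a
   mean of 39 years, 54% male).
2. **Phantom imaging** (`craniage.phantom`) — each subject rendered to a 3D
   volume (atlas ring + dens peg with exact landmark annotations; NIfTI
   I/O) and a 2D sagittal scanogram with sinus/clivus region masks.
3. **Morphometry** (`craniage.morphometry`) — the 26-feature scheme:
   17 sinus-geometry descriptors, 8 clivus brightness moment statistics
   (population central moments: mean, variance, SD, CV, m3, skewness, m4,
   excess kurtosis), plus the involution grade.
4. **Involution scale** (`craniage.involution`) — the 0–6 point rule-based
   grader on joint geometry and the grade → age-range lookup
   (0 → 14–20 y … 6 → over 71 y).
5. **ROI localisation** (`craniage.roi`) — a compact 2D CNN labels every
   axial/sagittal/coronal slice as crossing the joint region or not;
   positive labels aggregate to the ROI box
   `[Xm−64, Xm+64) × [Ym−64, Ym+64) × [Zm−STD, Zm+STD)`.
6. **Age regression** (`craniage.regression`) — ROI crops standardized to
   64³ cubes (32³ desk profile), a compact 3D CNN trained with Adam under
   cosine annealing, 4:1 train/test split, rotation/inversion/mirroring
   augmentations; error reported as RMSE in years.
7. **Statistics** (`craniage.stats`) — descriptive summaries,
   Kolmogorov–Smirnov normality and Mann–Whitney U tests, per-feature
   Pearson correlations with age, and the feature-correlation heatmap.
8. **Pipeline** (`craniage.pipeline`) — one-seed orchestration of all
   stages with a hashed artifact manifest.

The neural components run on a small pure-numpy network core
(`craniage.nnet`: strided conv2d/conv3d, Adam, cosine annealing), so
training is deterministic for a given seed and needs no GPU.

## Worked example

```python
import numpy as np
from craniage import CohortConfig, sample_cohort, grade_geometry
from craniage.stats import pearson

subjects = sample_cohort(CohortConfig())      # 223 subjects, default seed
ages = np.array([s.age_years for s in subjects])
grades = np.array([grade_geometry(s.geometry).points for s in subjects])
print(len(subjects), round(ages.mean(), 1))   # 223 38.7
print(round(pearson(grades, ages)[0], 3))     # 0.937
```

The grade–age correlation of 0.937 says the seven-point involution scale,
applied by deterministic rules to each subject's latent joint geometry,
orders the cohort by age almost as tightly as the generator's noise
allows. Running `examples/05_age_regression.py` trains the 3D regressor on
100 phantoms and prints

```
train: n=80, RMSE 11.0 y
test:  n=20, RMSE 8.9 y, MAE 7.9 y
```

i.e. the network recovers age from the rendered joint within single-digit
years on held-out phantoms. The `examples/` directory holds one short
script per capability (cohort/grading, phantom rendering, morphometry,
ROI localisation, regression, full pipeline).

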