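"""Sample the default synthetic cohort and grade every joint.

Generates the 223-subject study-condition cohort (ages 17-79, right-skewed
around 39 years, 54% male), applies the 0-6 involution scale to each
subject's latent joint geometry and prints the grade distribution and the
grade-age correlation.
"""

import numpy as np

from craniage import CohortConfig, grade_geometry, grade_to_age_range, sample_cohort
from craniage.stats import pearson

subjects = sample_cohort(CohortConfig())
ages = np.array([s.age_years for s in subjects])
grades = np.array([grade_geometry(s.geometry).points for s in subjects])

print(f"cohort: n={len(subjects)}, mean age {ages.mean():.1f} y, "
      f"range {ages.min():.0f}-{ages.max():.0f}")
for g in range(7):
    r = grade_to_age_range(g)
    hi = "open" if r.upper is None else f"{r.upper:.0f}"
    print(f"  grade {g} (ages {r.lower:.0f}-{hi}): {int((grades == g).sum())} subjects")

r, p = pearson(grades, ages)
print(f"Pearson r(grade, age) = {r:.3f} (p = {p:.2g})")
print("A correlation above 0.9 means the rule-based scale orders the cohort")
print("by age almost as well as the latent joint geometry allows.")
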