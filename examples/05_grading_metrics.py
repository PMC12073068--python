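"""Grading scores, the three correctness criteria, and inter-grader
agreement on a simulated cohort.

Grades use the 5-level clinical severity scale (0 none .. 4 proliferative
DR). A response is scored by its signed offset from the reference grade
and judged under three criteria: exact match, lenient (over-grading by one
tolerated), and referable agreement (both sides of the more-than-mild
boundary). Agreement across graders is Krippendorff's alpha with an
ordinal metric.
"""

import numpy as np

from retinagaze import (
    CohortConfig,
    accuracy,
    grade_score,
    krippendorff_alpha,
    simulate_cohort,
)
from retinagaze.metrics import UNGRADABLE

print("score examples: mild vs moderate reference ->", grade_score(1, 2))
print("                proliferative vs moderate  ->", grade_score(4, 2))

bundle = simulate_cohort(CohortConfig(n_participants=23, n_images=20, seed=7))
responses = bundle["responses"]
print(f"\ncohort: {len(responses)} responses "
      f"({responses['participant_id'].nunique()} graders x "
      f"{responses['image_id'].nunique()} images)")
for criterion in ("exact", "lenient", "referable"):
    print(f"  accuracy[{criterion:9s}] = {accuracy(responses, criterion):.3f}")

units = sorted(responses["image_id"].unique())
raters = sorted(responses["participant_id"].unique())
mat = np.full((len(units), len(raters)), np.nan)
for r in responses.itertuples():
    if r.grade != UNGRADABLE:
        mat[units.index(r.image_id), raters.index(r.participant_id)] = int(r.grade)
print(f"  Krippendorff alpha (ordinal) = {krippendorff_alpha(mat, 'ordinal'):.3f}")
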