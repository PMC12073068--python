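"""Search-pattern discovery: which scanpaths characterise correct and
incorrect grading?

Runs the full per-response pipeline on a small simulated cohort, splits
fixation strings by exact correctness, and clusters each group with
Affinity Propagation on Levenshtein distance. The exemplars are readable
canonical search patterns; structured (anatomy-led) responses collapse
onto the planted MSID pattern while saliency-driven ones fragment.
"""

from retinagaze import CohortConfig, compare_group_patterns, simulate_cohort
from retinagaze.metrics import correctness
from retinagaze.pipeline import RunConfig, process_response

bundle = simulate_cohort(CohortConfig(n_participants=6, n_images=6, seed=9))
config = RunConfig()

correct, incorrect = [], []
for r in bundle["responses"].itertuples():
    log = bundle["logs"][(r.participant_id, r.image_id)]
    fs, *_ = process_response(log, bundle["annotations"][r.image_id], config)
    if fs.pattern:
        (correct if correctness(r.grade, r.reference, "exact") else incorrect).append(
            fs.pattern
        )

report = compare_group_patterns(correct, incorrect, coverage=0.75)
for group in ("correct", "incorrect"):
    tops = report[group]["top"]
    print(f"{group} ({len(report[group]['clusters'])} clusters, "
          f"largest covering 75% of responses):")
    for c in tops[:5]:
        print(f"  {c.exemplar:10s} size {c.size}")
test = report["length_test"]
if test:
    print(f"exemplar length difference: U = {test.statistic:.1f}, p = {test.pvalue:.2f}")
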