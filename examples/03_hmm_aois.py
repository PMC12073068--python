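"""Data-driven areas of interest from gaze positions with a Gaussian HMM.

Gaze positions recorded while a clinician scans a fundus image cluster
around anatomical landmarks. A Gaussian-emission hidden Markov model
(state count selected by BIC) recovers those clusters; mapping each state
mean into the expanded annotation says which landmarks the response
covered.
"""

import numpy as np

from retinagaze import (
    StrategyProfile,
    clusters_to_aoi_report,
    expand_annotation,
    fit_gaze_hmm,
    generate_layout,
    invalidate_zoom_transitions,
    remap_to_image_coords,
    simulate_response,
)

annotation, _ = generate_layout(seed=3)
log, _ = simulate_response(StrategyProfile(), annotation, seed=4)
cleaned, _ = invalidate_zoom_transitions(log)
remapped = remap_to_image_coords(cleaned)
pts = remapped.loc[remapped["valid"], ["x", "y"]].to_numpy()

model, assignment = fit_gaze_hmm(pts, k_range=range(2, 7), seed=5)
print(f"BIC selected {model.n_states} states from {len(pts)} gaze samples")

report = clusters_to_aoi_report(model, expand_annotation(annotation))
for mean, label in zip(model.means, report["state_labels"]):
    print(f"  state mean ({mean[0]:6.1f}, {mean[1]:6.1f}) -> AOI {label}")
print(f"all four landmarks covered: {report['all_four_covered']}")
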