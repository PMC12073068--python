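"""Fixation detection and scanpath length on a simulated response.

Simulates a structured grading response (macula -> superior arcade ->
inferior arcade -> optic disc) at 150 Hz with zoom events and tracker
noise, cleans and remaps the log, detects fixations with the I-DT
dispersion algorithm, and sums the scanpath track length.
"""

from retinagaze import (
    StrategyProfile,
    detect_fixations_idt,
    generate_layout,
    invalidate_zoom_transitions,
    remap_to_image_coords,
    simulate_response,
    track_length,
)

annotation, geometry = generate_layout(seed=1)
log, truth = simulate_response(StrategyProfile(), annotation, seed=2)
print(f"raw log: {len(log)} samples at 150 Hz, "
      f"{log['zoom'].nunique()} zoom levels used")

cleaned, n_invalid = invalidate_zoom_transitions(log, window_ms=200.0)
remapped = remap_to_image_coords(cleaned, annotation.image_width, annotation.image_height)
fixations = detect_fixations_idt(remapped, dispersion_px=70.0, min_duration_ms=100.0)

print(f"invalidated {n_invalid} post-zoom samples; "
      f"detected {len(fixations)} fixations "
      f"(ground truth planned {len(truth['targets'])} targets)")
print(f"track length: {track_length(fixations):.0f} px "
      "(sum of distances between successive fixation centroids)")
for f in fixations[:3]:
    print(f"  fixation at ({f.x:6.1f}, {f.y:6.1f}), {f.duration:5.0f} ms")
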