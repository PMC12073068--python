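"""Zoom-aware gaze remapping and zoom-transition cleanup.

A grader pans and zooms over a fundus photograph; the tracker logs gaze as
a fraction of the displayed region plus the current viewport. Remapping
through the viewport recovers coordinates on the original, unzoomed image,
and samples recorded within 200 ms of a zoom change are invalidated
because the re-foveating saccade has not landed yet.
"""

import pandas as pd

from retinagaze import Viewport, invalidate_zoom_transitions, remap_point
from retinagaze.geometry import GAZE_LOG_COLUMNS

# Gaze at the centre of a 50x50-pixel visible region anchored at (200, 100)
vp = Viewport(origin_x=200, origin_y=100, width=50, height=50, zoom=1.0)
x, y = remap_point(0.5, 0.5, vp)
print(f"gaze at viewport centre -> original-image pixel ({x:.0f}, {y:.0f})")

# A log with a zoom change at t = 1000 ms: the two samples inside
# [1000, 1200] are discarded, the later one survives.
rows = [
    (900.0, 0.5, 0.5, True, 1.0, 0, 0, 1140, 848),
    (1000.0, 0.5, 0.5, True, 1.5, 285, 212, 760, 565),
    (1150.0, 0.5, 0.5, True, 1.5, 285, 212, 760, 565),
    (1300.0, 0.5, 0.5, True, 1.5, 285, 212, 760, 565),
]
log = pd.DataFrame(rows, columns=GAZE_LOG_COLUMNS)
cleaned, n = invalidate_zoom_transitions(log, window_ms=200.0)
print(f"invalidated {n} samples within 200 ms of the zoom change")
print(cleaned[["time_ms", "zoom", "valid"]].to_string(index=False))
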