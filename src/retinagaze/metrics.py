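"""Grading scores, correctness criteria, per-AOI gaze metrics, and zoom-time
profiles.

Severity grades follow the International Clinical Diabetic Retinopathy
Disease Severity Scale: 0 none, 1 mild NPDR, 2 moderate NPDR, 3 severe
NPDR, 4 proliferative DR, plus an "ungradable" response. A response's grade
score is its signed offset from the reference grade (-1 = one level less
severe). Three correctness criteria give the score clinical context:

EXACT      score == 0
LENIENT    score in {0, +1}: over-grading by one level may trigger an
           unnecessary referral but rarely harms the patient, so it is
           tolerated; under-grading is not
REFERABLE  grade and reference agree on referable DR (more than mild NPDR,
           i.e. level >= 2)

Ungradable responses count as incorrect under every criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .aoi import ANATOMICAL_LABELS, BACKGROUND
from .strings import _runs

__all__ = [
    "UNGRADABLE",
    "GRADE_NAMES",
    "Criterion",
    "grade_score",
    "is_referable",
    "correctness",
    "accuracy",
    "AOIMetrics",
    "aoi_metrics",
    "zoom_fractions",
]

#: Sentinel for an "ungradable" response (image quality judged too poor).
UNGRADABLE = "ungradable"

GRADE_NAMES = {
    0: "no DR",
    1: "mild NPDR",
    2: "moderate NPDR",
    3: "severe NPDR",
    4: "proliferative DR",
}

#: Referable DR is more than mild NPDR.
REFERABLE_THRESHOLD = 2


class Criterion(str, Enum):
    EXACT = "exact"
    LENIENT = "lenient"
    REFERABLE = "referable"


def _check_grade(grade) -> None:
    if grade != UNGRADABLE and grade not in GRADE_NAMES:
        raise ValueError(f"grade must be 0..4 or {UNGRADABLE!r}, got {grade!r}")


def grade_score(grade, reference) -> int | str:
    """Signed grade offset ``grade - reference``; ungradable propagates."""
    _check_grade(grade)
    _check_grade(reference)
    if reference == UNGRADABLE:
        raise ValueError("reference grade cannot be ungradable")
    if grade == UNGRADABLE:
        return UNGRADABLE
    return int(grade) - int(reference)


def is_referable(grade) -> bool:
    """True iff the grade is referable DR (moderate NPDR or worse)."""
    _check_grade(grade)
    if grade == UNGRADABLE:
        raise ValueError("referability undefined for an ungradable response")
    return int(grade) >= REFERABLE_THRESHOLD


def correctness(grade, reference, criterion: Criterion | str = Criterion.EXACT) -> bool:
    """Whether a response is correct under the given criterion (see module
    docstring). Ungradable responses are incorrect under all criteria."""
    criterion = Criterion(criterion)
    if grade == UNGRADABLE:
        _check_grade(reference)
        return False
    s = grade_score(grade, reference)
    if criterion is Criterion.EXACT:
        return s == 0
    if criterion is Criterion.LENIENT:
        return s in (0, 1)
    return is_referable(grade) == is_referable(reference)


def accuracy(responses: pd.DataFrame, criterion: Criterion | str = Criterion.EXACT) -> float:
    """Fraction of correct responses in a responses table (columns
    ``grade`` and ``reference``; ``grade`` may hold :data:`UNGRADABLE`)."""
    if len(responses) == 0:
        raise ValueError("empty responses table")
    flags = [
        correctness(g, r, criterion)
        for g, r in zip(responses["grade"], responses["reference"])
    ]
    return float(np.mean(flags))


@dataclass
class AOIMetrics:
    """Per-AOI gaze metrics for one grading response.

    For each label: ``fixation_count`` fixations resolved to it, ``visits``
    maximal runs in the resolved sequence, ``total_time`` summed fixation
    durations (seconds) and ``dwell_times`` one entry per visit (seconds).
    ``track_length`` is the response-level scanpath length in pixels.
    """

    fixation_count: dict[str, int] = field(default_factory=dict)
    visits: dict[str, int] = field(default_factory=dict)
    total_time: dict[str, float] = field(default_factory=dict)
    dwell_times: dict[str, list[float]] = field(default_factory=dict)
    track_length: float = 0.0


def aoi_metrics(
    resolved: list[str] | tuple[str, ...],
    durations_s: list[float],
    track_length_px: float = 0.0,
    merge_across_background: bool = False,
) -> AOIMetrics:
    """Per-AOI fixation counts, visits, total time, and dwell times.

    A visit is a maximal run of consecutive fixations resolved to the same
    label; its dwell time is the summed duration of those fixations. By
    default a background fixation terminates a visit; with
    ``merge_across_background=True`` background fixations are deleted first,
    so a visit continues across them (the B durations are not counted either
    way). Background itself is never reported.
    """
    if len(resolved) != len(durations_s):
        raise ValueError("resolved labels and durations must align")
    m = AOIMetrics(
        fixation_count={s: 0 for s in ANATOMICAL_LABELS},
        visits={s: 0 for s in ANATOMICAL_LABELS},
        total_time={s: 0.0 for s in ANATOMICAL_LABELS},
        dwell_times={s: [] for s in ANATOMICAL_LABELS},
        track_length=float(track_length_px),
    )
    pairs = list(zip(resolved, durations_s))
    if merge_across_background:
        pairs = [(s, d) for s, d in pairs if s != BACKGROUND]
    for sym, dur in pairs:
        if sym != BACKGROUND:
            m.fixation_count[sym] += 1
            m.total_time[sym] += float(dur)
    i = 0
    while i < len(pairs):
        sym = pairs[i][0]
        j = i
        dwell = 0.0
        while j < len(pairs) and pairs[j][0] == sym:
            dwell += float(pairs[j][1])
            j += 1
        if sym != BACKGROUND:
            m.visits[sym] += 1
            m.dwell_times[sym].append(dwell)
        i = j
    return m


def zoom_fractions(
    log: pd.DataFrame, max_gap_ms: float | None = None
) -> dict[float, float]:
    """Fraction of valid viewing time spent at each zoom level.

    Each valid sample is weighted by the interval to the next valid sample
    (the final sample gets the median interval). ``max_gap_ms`` caps the
    interval credited across gaps (e.g. invalidated zoom-transition
    windows); ``None`` leaves gaps attributed to the pre-gap level.

    Returns an empty dict when no valid time exists; otherwise the
    fractions sum to 1.
    """
    sub = log[log["valid"].astype(bool)]
    if len(sub) == 0:
        return {}
    t = sub["time_ms"].to_numpy(dtype=float)
    zoom = sub["zoom"].to_numpy(dtype=float)
    if len(sub) == 1:
        return {float(zoom[0]): 1.0}
    dt = np.diff(t)
    dt = np.append(dt, np.median(dt))
    if max_gap_ms is not None:
        dt = np.minimum(dt, max_gap_ms)
    total = dt.sum()
    out: dict[float, float] = {}
    for z in np.unique(zoom):
        out[float(z)] = float(dt[zoom == z].sum() / total)
    return out
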