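"""Readers and writers for the pipeline's plain-text table formats.

All tables are UTF-8 CSV with a mandatory header and '.' decimal
separator. The raw gaze log has one row per tracker sample; candidate AOI
labels in the labelled-fixation table are semicolon-separated symbols.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .geometry import GAZE_LOG_COLUMNS, Fixation
from .strings import FixationString, LabelledFixation

__all__ = [
    "read_gaze_log",
    "write_gaze_log",
    "read_fixations",
    "write_fixations",
    "read_labelled_fixations",
    "write_labelled_fixations",
    "write_strings_table",
    "read_strings_table",
    "read_responses",
    "write_responses",
]


def read_gaze_log(path: str | Path) -> pd.DataFrame:
    log = pd.read_csv(path)
    missing = set(GAZE_LOG_COLUMNS) - set(log.columns)
    if missing:
        raise ValueError(f"gaze log {path} missing columns {sorted(missing)}")
    log["valid"] = log["valid"].astype(bool)
    return log


def write_gaze_log(log: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    log[GAZE_LOG_COLUMNS + [c for c in log.columns if c not in GAZE_LOG_COLUMNS]].to_csv(
        path, index=False
    )


def write_fixations(
    fixations: list[Fixation], path: str | Path, **id_columns: str
) -> None:
    """Fixation table: x, y, onset_ms, duration_ms plus optional identifier
    columns (e.g. participant_id, image_id)."""
    df = pd.DataFrame(
        {
            "x": [f.x for f in fixations],
            "y": [f.y for f in fixations],
            "onset_ms": [f.onset for f in fixations],
            "duration_ms": [f.duration for f in fixations],
        }
    )
    for k, v in id_columns.items():
        df[k] = v
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_fixations(path: str | Path) -> list[Fixation]:
    df = pd.read_csv(path)
    return [
        Fixation(x=r.x, y=r.y, onset=r.onset_ms, duration=r.duration_ms)
        for r in df.itertuples()
    ]


def write_labelled_fixations(
    fixations: list[LabelledFixation], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "x": [f.x for f in fixations],
            "y": [f.y for f in fixations],
            "onset_ms": [f.onset for f in fixations],
            "duration_ms": [f.duration for f in fixations],
            "candidates": [";".join(sorted(f.candidates)) for f in fixations],
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_labelled_fixations(path: str | Path) -> list[LabelledFixation]:
    df = pd.read_csv(path)
    return [
        LabelledFixation(
            candidates=frozenset(str(r.candidates).split(";")),
            x=r.x,
            y=r.y,
            onset=r.onset_ms,
            duration=r.duration_ms,
        )
        for r in df.itertuples()
    ]


def write_strings_table(
    strings: list[FixationString],
    track_lengths: dict[str, float],
    path: str | Path,
) -> None:
    """Strings table: response_id, pattern, resolved_length, cost,
    track_length_px."""
    df = pd.DataFrame(
        {
            "response_id": [s.response_id for s in strings],
            "pattern": [s.pattern for s in strings],
            "resolved_length": [len(s.resolved) for s in strings],
            "cost": [s.cost for s in strings],
            "track_length_px": [track_lengths.get(s.response_id, 0.0) for s in strings],
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_strings_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["pattern"] = df["pattern"].fillna("").astype(str)
    return df


def read_responses(path: str | Path) -> pd.DataFrame:
    """Responses table: participant_id, image_id, profession, grade,
    reference, ungradable, decision_time_s. ``grade`` is read as object so
    the 'ungradable' sentinel survives."""
    df = pd.read_csv(path, dtype={"grade": object})
    df["grade"] = [
        g if g == "ungradable" else int(g) for g in df["grade"]
    ]
    df["reference"] = df["reference"].astype(int)
    return df


def write_responses(responses: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    responses.to_csv(path, index=False)
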