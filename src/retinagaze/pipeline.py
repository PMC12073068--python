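"""End-to-end orchestration: simulate (or load) a cohort, remap and clean
gaze, detect and label fixations, resolve strings, compute metrics and
statistics, and cluster search patterns into a summary report.

The heavy lifting lives in the other modules; this one wires stages
together under one config with per-stage logging and a single seed, and
writes every intermediate table so runs are auditable and reproducible
(identical config + seed -> identical outputs).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .aoi import ANATOMICAL_LABELS, AOIAnnotation, expand_annotation, label_fixation
from .clustering import ClusteringConfig, compare_group_patterns
from .geometry import (
    detect_fixations_idt,
    invalidate_zoom_transitions,
    remap_to_image_coords,
    track_length,
)
from .metrics import Criterion, UNGRADABLE, accuracy, aoi_metrics, zoom_fractions
from .stats import krippendorff_alpha, mann_whitney
from .strings import LabelledFixation, resolve_labels
from .synthetic import CohortConfig, simulate_cohort

__all__ = ["RunConfig", "process_response", "analyze_cohort", "run_pipeline"]

log = logging.getLogger("retinagaze")


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: cohort scale, cleaning and detection settings,
    correctness criterion, and clustering configuration.

    Round-trips through JSON unchanged (:meth:`to_json` / :meth:`from_json`);
    all randomness funnels through ``seed``.
    """

    n_participants: int = 23
    n_images: int = 20
    seed: int = 0
    window_ms: float = 200.0
    idt_dispersion_px: float = 70.0
    idt_min_duration_ms: float = 100.0
    expansion_radius_px: float = 70.0
    criterion: str = "exact"
    coverage: float = 0.75
    damping: float = 0.9
    max_cluster_group: int = 400

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def process_response(
    raw_log: pd.DataFrame,
    annotation: AOIAnnotation,
    config: RunConfig = RunConfig(),
    response_id: str = "",
):
    """Single-response pipeline: invalidate zoom windows, remap, detect
    fixations, label against the expanded annotation, and resolve the
    fixation string.

    Returns (fixation_string, labelled_fixations, fixations, n_invalidated).
    ``annotation`` may be raw or already expanded.
    """
    if not annotation.expanded:
        annotation = expand_annotation(annotation)
    cleaned, n_inv = invalidate_zoom_transitions(raw_log, window_ms=config.window_ms)
    remapped = remap_to_image_coords(
        cleaned, annotation.image_width, annotation.image_height
    )
    fixations = detect_fixations_idt(
        remapped,
        dispersion_px=config.idt_dispersion_px,
        min_duration_ms=config.idt_min_duration_ms,
    )
    labelled = [
        LabelledFixation(
            candidates=label_fixation(f.x, f.y, annotation),
            x=f.x,
            y=f.y,
            onset=f.onset,
            duration=f.duration,
        )
        for f in fixations
    ]
    fixation_string = resolve_labels(labelled, response_id=response_id)
    return fixation_string, labelled, fixations, n_inv


def _pool_metric(per_response: list, key: str, label: str) -> list[float]:
    vals = []
    for m in per_response:
        vals.append(float(getattr(m, key)[label]))
    return vals


def analyze_cohort(bundle: dict, config: RunConfig = RunConfig()) -> dict:
    """Run the full analysis on a simulated (or loaded) cohort bundle.

    Returns a report dict with grading accuracies under the three
    criteria, inter-grader agreement, zoom-time fractions, per-AOI
    correct-vs-incorrect comparisons, search-pattern clusters per group,
    and per-response tables (fixation strings, metrics).
    """
    responses: pd.DataFrame = bundle["responses"]
    annotations = {
        iid: (a if a.expanded else expand_annotation(a))
        for iid, a in bundle["annotations"].items()
    }
    log.info("analyze: %d responses, %d images", len(responses), len(annotations))

    strings = {}
    metrics = {}
    n_invalidated = 0
    zoom_profiles = []
    rows = []
    for r in responses.itertuples():
        rid = f"{r.participant_id}:{r.image_id}"
        raw = bundle["logs"][(r.participant_id, r.image_id)]
        fs, labelled, fixations, n_inv = process_response(
            raw, annotations[r.image_id], config, response_id=rid
        )
        n_invalidated += n_inv
        tl = track_length(fixations)
        m = aoi_metrics(
            list(fs.resolved),
            [f.duration / 1000.0 for f in labelled],
            track_length_px=tl,
        )
        strings[rid] = fs
        metrics[rid] = m
        cleaned, _ = invalidate_zoom_transitions(raw, window_ms=config.window_ms)
        zoom_profiles.append(zoom_fractions(cleaned))
        rows.append(
            {
                "response_id": rid,
                "pattern": fs.pattern,
                "resolved_length": len(fs.resolved),
                "cost": fs.cost,
                "track_length_px": tl,
                "n_fixations": len(fixations),
            }
        )
    strings_table = pd.DataFrame(rows)
    log.info("strings: %d resolved, %d samples invalidated", len(strings), n_invalidated)

    # grading accuracy and agreement
    acc = {c.value: accuracy(responses, c) for c in Criterion}
    units = sorted(responses["image_id"].unique())
    raters = sorted(responses["participant_id"].unique())
    mat = np.full((len(units), len(raters)), np.nan)
    for r in responses.itertuples():
        g = r.grade
        if g != UNGRADABLE:
            mat[units.index(r.image_id), raters.index(r.participant_id)] = int(g)
    alpha_grade = krippendorff_alpha(mat, level="ordinal")
    ref_mat = np.where(np.isnan(mat), np.nan, (mat >= 2).astype(float))
    alpha_referable = krippendorff_alpha(ref_mat, level="nominal")

    # pooled zoom-time fractions
    zoom_all: dict[float, float] = {}
    for prof in zoom_profiles:
        for z, f in prof.items():
            zoom_all[z] = zoom_all.get(z, 0.0) + f
    total = sum(zoom_all.values())
    zoom_all = {z: f / total for z, f in sorted(zoom_all.items())} if total else {}

    # correct vs incorrect per-AOI comparisons
    crit = Criterion(config.criterion)
    correct_ids, incorrect_ids = [], []
    for r in responses.itertuples():
        rid = f"{r.participant_id}:{r.image_id}"
        from .metrics import correctness

        (correct_ids if correctness(r.grade, r.reference, crit) else incorrect_ids).append(rid)

    comparisons = {}
    for label in ANATOMICAL_LABELS + ("all",):
        labs = list(ANATOMICAL_LABELS) if label == "all" else [label]
        entry = {}
        for key in ("fixation_count", "visits", "total_time"):
            a = [v for lab in labs for v in _pool_metric([metrics[i] for i in correct_ids], key, lab)]
            b = [v for lab in labs for v in _pool_metric([metrics[i] for i in incorrect_ids], key, lab)]
            entry[key] = mann_whitney(a, b) if a and b else None
        # dwell times pool individual visit durations
        a = [d for lab in labs for i in correct_ids for d in metrics[i].dwell_times[lab]]
        b = [d for lab in labs for i in incorrect_ids for d in metrics[i].dwell_times[lab]]
        entry["dwell_time"] = mann_whitney(a, b) if a and b else None
        comparisons[label] = entry
    tl_a = [metrics[i].track_length for i in correct_ids]
    tl_b = [metrics[i].track_length for i in incorrect_ids]
    track_test = mann_whitney(tl_a, tl_b) if tl_a and tl_b else None

    # search-pattern clustering per group (non-empty patterns only)
    def _patterns(ids):
        return [strings[i].pattern for i in ids if strings[i].pattern]

    pc, pi = _patterns(correct_ids), _patterns(incorrect_ids)
    rng = np.random.default_rng(config.seed)
    if len(pc) > config.max_cluster_group:
        pc = [pc[i] for i in rng.choice(len(pc), config.max_cluster_group, replace=False)]
    if len(pi) > config.max_cluster_group:
        pi = [pi[i] for i in rng.choice(len(pi), config.max_cluster_group, replace=False)]
    if pc and pi:
        patterns = compare_group_patterns(
            pc,
            pi,
            config=ClusteringConfig(damping=config.damping, seed=config.seed),
            coverage=config.coverage,
        )
    else:
        patterns = None
    log.info("clusters: correct=%d incorrect=%d strings", len(pc), len(pi))

    return {
        "accuracy": acc,
        "alpha_grade": alpha_grade,
        "alpha_referable": alpha_referable,
        "zoom_fractions": zoom_all,
        "comparisons": comparisons,
        "track_length_test": track_test,
        "patterns": patterns,
        "strings_table": strings_table,
        "metrics": metrics,
        "strings": strings,
        "n_invalidated": n_invalidated,
        "correct_ids": correct_ids,
        "incorrect_ids": incorrect_ids,
    }


def _jsonable(obj):
    from .clustering import StringCluster
    from .stats import TestResult

    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, TestResult):
        return {"statistic": obj.statistic, "pvalue": obj.pvalue}
    if isinstance(obj, StringCluster):
        return {"exemplar": obj.exemplar, "size": obj.size, "members": obj.members}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Simulate a cohort under ``config``, analyse it end to end, and write
    every table plus a JSON summary report to ``out_dir``.

    Writes: ``config.json``, ``responses.csv``, per-response gaze logs
    under ``logs/``, annotations under ``annotations/``, ``strings.csv``,
    ``metrics.csv`` (one row per response x label) and ``report.json``.
    Returns the in-memory report from :func:`analyze_cohort`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")

    cohort = CohortConfig(
        n_participants=config.n_participants,
        n_images=config.n_images,
        seed=config.seed,
    )
    bundle = simulate_cohort(cohort)
    log.info("simulate: %d responses", len(bundle["responses"]))
    rio.write_responses(bundle["responses"], out / "responses.csv")
    for (pid, iid), glog in bundle["logs"].items():
        rio.write_gaze_log(glog, out / "logs" / f"{pid}_{iid}.csv")
    for iid, ann in bundle["annotations"].items():
        ann.save(out / "annotations" / f"{iid}.json")

    report = analyze_cohort(bundle, config)
    report["strings_table"].to_csv(out / "strings.csv", index=False)

    mrows = []
    for rid, m in report["metrics"].items():
        for lab in ANATOMICAL_LABELS:
            mrows.append(
                {
                    "response_id": rid,
                    "label": lab,
                    "fixation_count": m.fixation_count[lab],
                    "visits": m.visits[lab],
                    "total_time_s": m.total_time[lab],
                    "mean_dwell_s": float(np.mean(m.dwell_times[lab])) if m.dwell_times[lab] else 0.0,
                    "track_length_px": m.track_length,
                }
            )
    pd.DataFrame(mrows).to_csv(out / "metrics.csv", index=False)

    summary = {
        k: _jsonable(report[k])
        for k in (
            "accuracy",
            "alpha_grade",
            "alpha_referable",
            "zoom_fractions",
            "comparisons",
            "track_length_test",
            "patterns",
            "n_invalidated",
        )
    }
    (out / "report.json").write_text(json.dumps(summary, indent=1))
    return report
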