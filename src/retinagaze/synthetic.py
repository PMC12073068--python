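"""Synthetic screening cohorts with known ground truth.

The study's recordings are not public, so this module generates complete
synthetic datasets for every pipeline stage: schematic posterior-pole AOI
layouts (disc, macula, two arcades), raw gaze logs with zoom events and
tracker noise sampled at the tracker rate, and grading-response tables with
a configurable grade-confusion distribution. Defaults mirror the study
conditions: 23 participants each grading 20 images (four per severity
grade), 150 Hz sampling, 1.5**k zoom ladder, and an exact-agreement
probability of 0.648.

Two scanpath strategies are simulated. A *structured* response walks a
canonical anatomical sequence (default "MSID": macula, superior arcade,
inferior arcade, optic disc), fixating each AOI a few times with Gaussian
scatter. A *saliency* response fixates random "salient" points with a
nasal-to-temporal drift, unrelated to the anatomical landmarks; it is a
minimal stand-in for stimulus-driven search, not a quantitative saliency
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import line as draw_line

from .aoi import ANATOMICAL_LABELS, AOIAnnotation, RetinalGeometry, macula_mask
from .geometry import GAZE_LOG_COLUMNS, Viewport, zoom_level
from .metrics import UNGRADABLE
from .strings import collapse_runs

__all__ = [
    "StrategyProfile",
    "CohortConfig",
    "ZoomConfig",
    "generate_layout",
    "simulate_response",
    "simulate_cohort",
    "DEFAULT_GRADE_CONFUSION",
]

#: Default grade-confusion distribution: probability of each signed grade
#: offset, plus the ungradable rate. P(0) = 0.648 and P(0) + P(+1) = 0.809
#: reproduce the study-level exact and lenient agreement; the ungradable
#: rate is 0.7%.
DEFAULT_GRADE_CONFUSION = {
    -2: 0.034,
    -1: 0.120,
    0: 0.648,
    1: 0.161,
    2: 0.030,
    UNGRADABLE: 0.007,
}

#: Default time fractions at each zoom step count (zoom = 1.5**k): roughly a
#: third zoomed out, a quarter at low zoom, a third at high zoom, with
#: moderate and very high zoom rare.
DEFAULT_ZOOM_LEVEL_WEIGHTS = {0: 0.34, 1: 0.26, 2: 0.05, 3: 0.33, 4: 0.02}


@dataclass(frozen=True)
class StrategyProfile:
    """Generative parameters of one scanpath strategy.

    ``fixation_noise_sd`` (px) scatters fixation targets around the AOI
    sample point; ``duration_log_mean``/``duration_log_sd`` parameterise a
    lognormal fixation duration in log-seconds (defaults give a median of
    ~0.27 s); ``fixations_per_aoi`` is an inclusive uniform range.
    """

    kind: str = "structured"
    canonical_sequence: str = "MSID"
    fixations_per_aoi: tuple[int, int] = (2, 4)
    fixation_noise_sd: float = 20.0
    duration_log_mean: float = math.log(0.27)
    duration_log_sd: float = 0.35
    n_salient_points: int = 8

    def __post_init__(self) -> None:
        if self.kind not in ("structured", "saliency"):
            raise ValueError("kind must be 'structured' or 'saliency'")
        if self.kind == "structured":
            if not self.canonical_sequence or set(self.canonical_sequence) - set(
                ANATOMICAL_LABELS
            ):
                raise ValueError("canonical_sequence must be non-empty over D/M/S/I")
        if self.fixation_noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


@dataclass(frozen=True)
class ZoomConfig:
    """Zoom behaviour of a simulated response.

    ``event_rate`` is the expected number of zoom-level changes per
    response; target levels are drawn from ``level_weights`` (keys are the
    step count k, zoom = 1.5**k). On a change the viewport recentres on the
    current fixation target, clamped to the image; while zoomed, each new
    fixation pans (recentres) without a zoom change.
    """

    event_rate: float = 3.0
    level_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ZOOM_LEVEL_WEIGHTS)
    )
    sample_rate_hz: float = 150.0
    tracker_jitter_px: float = 6.0
    blink_rate: float = 0.05
    settle_ms: float = 250.0


@dataclass(frozen=True)
class CohortConfig:
    """Study-scale defaults: 23 graders x 20 images, four images per
    severity grade, offset-based grade confusion, and a strategy mix where
    correct responses are predominantly structured."""

    n_participants: int = 23
    n_images: int = 20
    reference_grades: tuple[int, ...] | None = None
    grade_confusion: dict = field(default_factory=lambda: dict(DEFAULT_GRADE_CONFUSION))
    strategy_mix: dict = field(default_factory=lambda: {True: 0.85, False: 0.35})
    zoom: ZoomConfig = field(default_factory=ZoomConfig)
    structured: StrategyProfile = field(default_factory=StrategyProfile)
    saliency: StrategyProfile = field(
        default_factory=lambda: StrategyProfile(kind="saliency")
    )
    image_width: int = 1140
    image_height: int = 848
    n_optometrists: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.grade_confusion.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"grade-confusion probabilities sum to {total}, not 1")

    def references(self) -> list[int]:
        if self.reference_grades is not None:
            if len(self.reference_grades) != self.n_images:
                raise ValueError("reference_grades length must equal n_images")
            return list(self.reference_grades)
        # four images per grade level by default; extras cycle
        return [i % 5 for i in range(self.n_images)]


# ---------------------------------------------------------------------------
# Layout generation


def _rasterize_polyline(points: np.ndarray, shape: tuple[int, int], width: int = 3) -> np.ndarray:
    """Rasterize a polyline (n, 2) of (x, y) vertices at the given stroke
    width by stamping Bresenham lines then dilating with a small square."""
    mask = np.zeros(shape, dtype=bool)
    pts = np.round(points).astype(int)
    h, w = shape
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(y0, x0, y1, x1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        mask[rr[keep], cc[keep]] = True
    if width > 1:
        from scipy import ndimage

        mask = ndimage.binary_dilation(mask, iterations=width // 2)
    return mask


def generate_layout(
    image_width: int = 1140,
    image_height: int = 848,
    seed: int = 0,
    image_id: str = "synthetic",
    expansion_radius_px: float = 70.0,
) -> tuple[AOIAnnotation, RetinalGeometry]:
    """Generate a schematic posterior-pole AOI layout (synthetic stand-in
    for an annotated fundus photograph).

    The optic disc sits nasally (large x), the foveola 4.76 mm temporal to
    it at a scale chosen so the posterior pole fills the image, the macula
    is the standard 5.5 mm circle, and the temporal arcades are parabolic
    vessel arcs from the disc margin around the macula, rasterized 3 px
    wide. Masks are non-degenerate and mutually disjoint before expansion.
    A little seeded jitter varies positions between images.
    """
    if image_width < 600 or image_height < 400:
        raise ValueError("image must be at least 600 x 400 px")
    rng = np.random.default_rng(seed)
    px_per_mm = image_width / 15.0  # posterior-pole field of ~15 mm across
    jitter = rng.uniform(-0.02, 0.02, size=4)
    fovea = np.array(
        [
            image_width * (0.40 + jitter[0]),
            image_height * (0.50 + jitter[1]),
        ]
    )
    angle = math.radians(rng.uniform(-4.0, 4.0))
    disc = fovea + 4.76 * px_per_mm * np.array([math.cos(angle), -math.sin(angle)])
    geometry = RetinalGeometry(disc_center=tuple(disc), foveola=tuple(fovea))

    shape = (image_height, image_width)
    yy, xx = np.mgrid[0:image_height, 0:image_width]

    disc_radius = 0.92 * px_per_mm  # ~1.84 mm disc diameter
    disc_mask = (xx - disc[0]) ** 2 + (yy - disc[1]) ** 2 <= disc_radius**2
    mac_mask = macula_mask(geometry, image_width, image_height)

    # Temporal arcades: vessel arcs starting at the disc margin and curving
    # around the macula at a radius that clears the expanded macula, so the
    # raw masks stay disjoint and each arcade keeps unambiguous core pixels
    # after the tracker-accuracy expansion.
    mac_radius = (geometry.macula_diameter_mm / 2) * geometry.px_per_mm
    apex_r = mac_radius + expansion_radius_px + 0.7 * px_per_mm
    disc_r_from_fovea = float(np.hypot(*(disc - fovea)))
    masks = {"D": disc_mask, "M": mac_mask}
    base_angle = math.degrees(math.atan2(-(disc[1] - fovea[1]), disc[0] - fovea[0]))
    for sym, sign in (("S", 1.0), ("I", -1.0)):
        theta = np.radians(base_angle + sign * np.linspace(14.0, 165.0, 80))
        s = np.linspace(0.0, 1.0, 80)
        radius = apex_r + (disc_r_from_fovea - 6 - apex_r) * (2 * (s - 0.5)) ** 2
        x = fovea[0] + radius * np.cos(theta)
        y = fovea[1] - radius * np.sin(theta)  # image y grows downward
        x = np.clip(x, 2, image_width - 3)
        y = np.clip(y, 2, image_height - 3)
        arc = _rasterize_polyline(np.column_stack([x, y]), shape, width=3)
        arc &= ~(disc_mask | mac_mask)  # keep raw masks disjoint
        masks[sym] = arc

    annotation = AOIAnnotation(
        image_id=image_id,
        image_width=image_width,
        image_height=image_height,
        masks=masks,
        expansion_radius_px=expansion_radius_px,
        expanded=False,
        geometry=geometry,
    )
    for sym, m in masks.items():
        if not m.any():
            raise RuntimeError(f"degenerate layout: empty {sym} mask")
    return annotation, geometry


# ---------------------------------------------------------------------------
# Response simulation


def _sample_mask_point(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    i = rng.integers(len(rows))
    return np.array([cols[i], rows[i]], dtype=float)


def _plan_fixations(
    profile: StrategyProfile,
    annotation: AOIAnnotation,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Fixation targets (n, 2), true AOI symbols, durations (s)."""
    w, h = annotation.image_width, annotation.image_height
    targets: list[np.ndarray] = []
    labels: list[str] = []
    lo, hi = profile.fixations_per_aoi
    if profile.kind == "structured":
        # A deliberate look at a landmark aims at the landmark itself, so
        # bases come from the AOI's unambiguous core; tracker noise around
        # the base still produces the occasional multi-AOI fixation.
        from .aoi import core_masks

        cores = core_masks(annotation)
        for sym in profile.canonical_sequence:
            src = cores[sym] if cores[sym].any() else annotation.masks[sym]
            base = _sample_mask_point(src, rng)
            for _ in range(int(rng.integers(lo, hi + 1))):
                p = base + rng.normal(0.0, profile.fixation_noise_sd, size=2)
                p[0] = np.clip(p[0], 0, w - 1)
                p[1] = np.clip(p[1], 0, h - 1)
                targets.append(p)
                labels.append(sym)
    else:
        pts = np.column_stack(
            [
                rng.uniform(0.08 * w, 0.92 * w, size=profile.n_salient_points),
                rng.uniform(0.08 * h, 0.92 * h, size=profile.n_salient_points),
            ]
        )
        pts = pts[np.argsort(-pts[:, 0])]  # nasal (disc side) to temporal drift
        for base in pts:
            for _ in range(int(rng.integers(lo, hi + 1))):
                p = base + rng.normal(0.0, profile.fixation_noise_sd, size=2)
                p[0] = np.clip(p[0], 0, w - 1)
                p[1] = np.clip(p[1], 0, h - 1)
                targets.append(p)
                labels.append("?")
    durations = rng.lognormal(
        profile.duration_log_mean, profile.duration_log_sd, size=len(targets)
    )
    return np.array(targets), labels, durations


def _viewport_for(
    target: np.ndarray, k: int, image_width: int, image_height: int
) -> Viewport:
    """Viewport at zoom 1.5**k recentred on ``target``, clamped to the
    image."""
    z = zoom_level(k)
    vw, vh = image_width / z, image_height / z
    ox = float(np.clip(target[0] - vw / 2, 0, image_width - vw))
    oy = float(np.clip(target[1] - vh / 2, 0, image_height - vh))
    return Viewport(origin_x=ox, origin_y=oy, width=vw, height=vh, zoom=z)


def simulate_response(
    profile: StrategyProfile,
    annotation: AOIAnnotation,
    zoom: ZoomConfig = ZoomConfig(),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one grading response: a raw gaze log plus ground truth.

    Samples are emitted at ``zoom.sample_rate_hz`` with strictly increasing
    timestamps. Fixation samples scatter around the target with a fixed
    screen-pixel jitter (so image-space jitter shrinks when zoomed in);
    saccades between fixations are linearly interpolated at the sample rate
    and are fast enough for the dispersion criterion to reject. Zoom
    changes recentre the viewport on the current target and are followed by
    ``settle_ms`` of settling samples, mirroring the re-foveation period
    that post-processing invalidates. Occasional short blink bursts are
    flagged invalid by the tracker.

    Returns the raw log (columns :data:`~retinagaze.geometry.GAZE_LOG_COLUMNS`)
    and a truth dict with ``targets``, ``labels``, ``durations_s``,
    ``pattern`` (structured profiles) and the per-fixation ``zoom_steps``.
    """
    rng = np.random.default_rng(seed)
    w, h = annotation.image_width, annotation.image_height
    targets, labels, durations = _plan_fixations(profile, annotation, rng)
    n_fix = len(targets)

    # zoom schedule: event count ~ Poisson(event_rate) change points
    steps = np.zeros(n_fix, dtype=int)
    n_events = rng.poisson(zoom.event_rate)
    ks = list(zoom.level_weights)
    pk = np.array([zoom.level_weights[k] for k in ks], dtype=float)
    pk /= pk.sum()
    if n_fix > 1 and n_events > 0:
        change_at = np.sort(rng.choice(np.arange(1, n_fix), size=min(n_events, n_fix - 1), replace=False))
        current = 0
        ci = 0
        for i in range(n_fix):
            if ci < len(change_at) and i == change_at[ci]:
                new = int(rng.choice(ks, p=pk))
                if new == current:  # force an actual change
                    new = int(rng.choice([k for k in ks if k != current]))
                current = new
                ci += 1
            steps[i] = current

    dt_ms = 1000.0 / zoom.sample_rate_hz
    jitter_frac = zoom.tracker_jitter_px / w  # screen-space jitter as a fraction

    rows_t: list[float] = []
    rows: list[tuple] = []
    t = 0.0

    def emit(pos: np.ndarray, vp: Viewport, n: int, valid: bool, jitter: bool) -> None:
        nonlocal t
        for _ in range(n):
            fx = (pos[0] - vp.origin_x) / vp.width
            fy = (pos[1] - vp.origin_y) / vp.height
            if jitter:
                fx += rng.normal(0.0, jitter_frac)
                fy += rng.normal(0.0, jitter_frac)
            fx = float(np.clip(fx, 0.0, 1.0))
            fy = float(np.clip(fy, 0.0, 1.0))
            rows.append(
                (t, fx, fy, valid, vp.zoom, vp.origin_x, vp.origin_y, vp.width, vp.height)
            )
            t += dt_ms

    prev_target: np.ndarray | None = None
    prev_step = 0
    vp = _viewport_for(np.array([w / 2, h / 2]), 0, w, h)
    for i in range(n_fix):
        target = targets[i]
        if steps[i] != prev_step:
            vp = _viewport_for(target, int(steps[i]), w, h)
            prev_step = int(steps[i])
            n_settle = max(1, int(round(zoom.settle_ms / dt_ms)))
            emit(target, vp, n_settle, True, jitter=True)
        elif steps[i] > 0:
            vp = _viewport_for(target, int(steps[i]), w, h)  # pan, no zoom change
        if prev_target is not None:
            # saccade: ~30 ms of interpolated samples
            n_sacc = max(1, int(round(30.0 / dt_ms)))
            for s in range(1, n_sacc + 1):
                pos = prev_target + (target - prev_target) * s / (n_sacc + 1)
                pos = np.clip(pos, [vp.origin_x, vp.origin_y],
                              [vp.origin_x + vp.width, vp.origin_y + vp.height])
                emit(pos, vp, 1, True, jitter=False)
            if rng.random() < zoom.blink_rate:
                emit(target, vp, int(round(100.0 / dt_ms)), False, jitter=False)
        n_samples = max(1, int(round(durations[i] * 1000.0 / dt_ms)))
        emit(target, vp, n_samples, True, jitter=True)
        prev_target = target

    log = pd.DataFrame(rows, columns=GAZE_LOG_COLUMNS)
    truth = {
        "targets": targets,
        "labels": labels,
        "durations_s": durations,
        "zoom_steps": steps,
        "pattern": collapse_runs(labels) if profile.kind == "structured" else None,
        "kind": profile.kind,
    }
    return log, truth


# ---------------------------------------------------------------------------
# Cohort simulation


def _draw_grade(reference: int, confusion: dict, rng: np.random.Generator):
    """Draw a grade around the reference from the offset distribution.

    Offsets that would leave the 0-4 scale are reflected (|offset| kept,
    sign flipped), which preserves P(score = 0) at every reference grade so
    the cohort's exact accuracy matches the configured P(0).
    """
    keys = list(confusion)
    p = np.array([confusion[k] for k in keys], dtype=float)
    p /= p.sum()
    off = keys[int(rng.choice(len(keys), p=p))]
    if off == UNGRADABLE:
        return UNGRADABLE
    g = reference + off
    if g < 0 or g > 4:
        g = reference - off
    return int(np.clip(g, 0, 4))


def simulate_cohort(config: CohortConfig = CohortConfig()) -> dict:
    """Simulate a full cohort: layouts, gaze logs, and grading responses.

    Every participant grades every image. The grade is drawn from the
    offset confusion distribution around the image's reference grade;
    whether the response then follows the structured or the saliency
    strategy depends on its exact correctness through ``strategy_mix``.
    Deterministic per ``config.seed``.

    Returns a bundle dict:

    - ``annotations``: per-image unexpanded :class:`AOIAnnotation`
    - ``responses``: DataFrame (participant_id, image_id, profession,
      grade, reference, ungradable, decision_time_s, strategy)
    - ``logs``: dict keyed by (participant_id, image_id) of raw gaze logs
    - ``truth``: dict keyed likewise with per-response ground truth
    """
    rng = np.random.default_rng(config.seed)
    refs = config.references()
    annotations = {}
    for i in range(config.n_images):
        ann, _ = generate_layout(
            config.image_width,
            config.image_height,
            seed=int(rng.integers(2**31 - 1)),
            image_id=f"img{i:03d}",
        )
        annotations[f"img{i:03d}"] = ann

    rows = []
    logs: dict[tuple[str, str], pd.DataFrame] = {}
    truths: dict[tuple[str, str], dict] = {}
    for p in range(config.n_participants):
        pid = f"p{p:02d}"
        profession = "optometrist" if p < config.n_optometrists else "ophthalmologist"
        for i in range(config.n_images):
            iid = f"img{i:03d}"
            ref = refs[i]
            grade = _draw_grade(ref, config.grade_confusion, rng)
            correct = grade != UNGRADABLE and int(grade) == ref
            structured = rng.random() < config.strategy_mix[bool(correct)]
            profile = config.structured if structured else config.saliency
            log, truth = simulate_response(
                profile,
                annotations[iid],
                zoom=config.zoom,
                seed=int(rng.integers(2**31 - 1)),
            )
            logs[(pid, iid)] = log
            truths[(pid, iid)] = truth
            rows.append(
                {
                    "participant_id": pid,
                    "image_id": iid,
                    "profession": profession,
                    "grade": grade,
                    "reference": ref,
                    "ungradable": grade == UNGRADABLE,
                    "decision_time_s": float(rng.lognormal(3.0, 0.4)),
                    "strategy": profile.kind,
                }
            )
    return {
        "annotations": annotations,
        "responses": pd.DataFrame(rows),
        "logs": logs,
        "truth": truths,
        "config": config,
    }
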