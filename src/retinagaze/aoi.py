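"""Areas of interest on the posterior pole: annotations, expansion, and
data-driven derivation from gaze with Gaussian hidden Markov models.

Four anatomical landmarks serve as AOIs — the optic disc (D), macula (M),
superior temporal arcade (S) and inferior temporal arcade (I) — plus a
background symbol (B) for fixations matching none. Annotated pixel masks are
dilated by the tracker-accuracy radius so gaze within tracker error of an
annotation still counts as aligned; dilated masks may overlap, which is
resolved downstream by the fixation-string layer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM
from scipy import ndimage

__all__ = [
    "AOI_LABELS",
    "ANATOMICAL_LABELS",
    "BACKGROUND",
    "AOIAnnotation",
    "RetinalGeometry",
    "GazeHMM",
    "macula_mask",
    "expand_annotation",
    "label_fixation",
    "fit_gaze_hmm",
    "clusters_to_aoi_report",
]

#: Full AOI alphabet: optic disc, macula, superior arcade, inferior arcade,
#: background. B never appears in exported pattern strings.
AOI_LABELS = ("D", "M", "S", "I", "B")
ANATOMICAL_LABELS = ("D", "M", "S", "I")
BACKGROUND = "B"


@dataclass(frozen=True)
class RetinalGeometry:
    """Anatomical scale anchors for a fundus image.

    The millimetre scale of a fundus photograph is recovered from the
    disc–fovea distance: the foveola lies 4.76 mm from the centre of the
    optic disc, and the macula is modelled as a 5.5 mm diameter circle
    centred on the foveola.
    """

    disc_center: tuple[float, float]
    foveola: tuple[float, float]
    disc_fovea_mm: float = 4.76
    macula_diameter_mm: float = 5.5

    @property
    def px_per_mm(self) -> float:
        d = float(np.hypot(
            self.disc_center[0] - self.foveola[0],
            self.disc_center[1] - self.foveola[1],
        ))
        if d == 0:
            raise ValueError("disc centre coincides with foveola: scale undefined")
        return d / self.disc_fovea_mm

    def to_dict(self) -> dict:
        return {
            "disc_center": list(self.disc_center),
            "foveola": list(self.foveola),
            "disc_fovea_mm": self.disc_fovea_mm,
            "macula_diameter_mm": self.macula_diameter_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RetinalGeometry":
        return cls(
            disc_center=tuple(d["disc_center"]),
            foveola=tuple(d["foveola"]),
            disc_fovea_mm=float(d.get("disc_fovea_mm", 4.76)),
            macula_diameter_mm=float(d.get("macula_diameter_mm", 5.5)),
        )


@dataclass
class AOIAnnotation:
    """Per-image AOI annotation: one binary raster per anatomical label.

    ``masks`` maps label symbols to boolean arrays of shape
    ``(image_height, image_width)`` (row = y, column = x). ``expanded`` is
    False for raw annotations and True once masks have been dilated by
    ``expansion_radius_px``; only expanded annotations should be used for
    fixation labelling.
    """

    image_id: str
    image_width: int
    image_height: int
    masks: dict[str, np.ndarray]
    expansion_radius_px: float = 70.0
    expanded: bool = False
    geometry: RetinalGeometry | None = None

    def __post_init__(self) -> None:
        for sym, m in self.masks.items():
            if sym not in ANATOMICAL_LABELS:
                raise ValueError(f"unknown AOI symbol {sym!r}")
            if m.shape != (self.image_height, self.image_width):
                raise ValueError(f"mask {sym} shape {m.shape} does not match image size")

    def background_mask(self) -> np.ndarray:
        """B is the complement of the union of the label masks."""
        union = np.zeros((self.image_height, self.image_width), dtype=bool)
        for m in self.masks.values():
            union |= m
        return ~union

    def save(self, path: str | Path) -> None:
        """Write the JSON sidecar + one PNG label image per AOI."""
        from PIL import Image

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        labels = []
        for sym, m in self.masks.items():
            mask_file = f"{path.stem}_{sym}.png"
            Image.fromarray((m.astype(np.uint8)) * 255).save(path.parent / mask_file)
            labels.append({"symbol": sym, "mask_file": mask_file})
        sidecar = {
            "image_id": self.image_id,
            "width": self.image_width,
            "height": self.image_height,
            "labels": labels,
            "expansion_radius_px": self.expansion_radius_px,
            "expanded": self.expanded,
        }
        if self.geometry is not None:
            sidecar["geometry"] = self.geometry.to_dict()
        path.write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "AOIAnnotation":
        from PIL import Image

        path = Path(path)
        sidecar = json.loads(path.read_text())
        masks = {}
        for entry in sidecar["labels"]:
            img = Image.open(path.parent / entry["mask_file"])
            masks[entry["symbol"]] = np.asarray(img) > 0
        geom = sidecar.get("geometry")
        return cls(
            image_id=sidecar["image_id"],
            image_width=int(sidecar["width"]),
            image_height=int(sidecar["height"]),
            masks=masks,
            expansion_radius_px=float(sidecar.get("expansion_radius_px", 70.0)),
            expanded=bool(sidecar.get("expanded", False)),
            geometry=RetinalGeometry.from_dict(geom) if geom else None,
        )


def core_masks(annotation: AOIAnnotation) -> dict[str, np.ndarray]:
    """Pixels of each raw mask that stay unambiguous after expansion.

    The core of a label is its unexpanded mask minus every other label's
    expanded mask — a gaze landing there matches exactly one AOI. Computed
    once per annotation and cached on the instance.
    """
    cached = getattr(annotation, "_core_cache", None)
    if cached is not None:
        return cached
    r = annotation.expansion_radius_px
    expanded = {}
    for sym, m in annotation.masks.items():
        if r == 0 or not m.any():
            expanded[sym] = m
        else:
            expanded[sym] = ndimage.distance_transform_edt(~m) <= r
    cores = {}
    for sym, m in annotation.masks.items():
        core = m.copy()
        for other, em in expanded.items():
            if other != sym:
                core &= ~em
        cores[sym] = core
    annotation._core_cache = cores
    return cores


def macula_mask(
    geometry: RetinalGeometry, image_width: int, image_height: int
) -> np.ndarray:
    """Binary raster of the macula: a circle of ``macula_diameter_mm``
    centred on the foveola, at the scale set by the disc–fovea distance,
    clipped to the image."""
    radius = (geometry.macula_diameter_mm / 2.0) * geometry.px_per_mm
    yy, xx = np.mgrid[0:image_height, 0:image_width]
    fx, fy = geometry.foveola
    return (xx - fx) ** 2 + (yy - fy) ** 2 <= radius**2


def expand_annotation(annotation: AOIAnnotation) -> AOIAnnotation:
    """Dilate every label mask by a Euclidean disc of
    ``expansion_radius_px``, accounting for tracker accuracy.

    Uses the exact Euclidean distance transform, so the expanded mask is
    precisely the set of pixels within the radius of an annotated pixel.
    Expanded masks may overlap; overlap is resolved at the string stage.
    """
    r = annotation.expansion_radius_px
    if r < 0:
        raise ValueError("expansion radius must be >= 0")
    new_masks = {}
    for sym, m in annotation.masks.items():
        if r == 0 or not m.any():
            new_masks[sym] = m.copy()
        else:
            dist = ndimage.distance_transform_edt(~m)
            new_masks[sym] = dist <= r
    return AOIAnnotation(
        image_id=annotation.image_id,
        image_width=annotation.image_width,
        image_height=annotation.image_height,
        masks=new_masks,
        expansion_radius_px=r,
        expanded=True,
        geometry=annotation.geometry,
    )


def label_fixation(x: float, y: float, annotation: AOIAnnotation) -> frozenset[str]:
    """All AOI labels whose (expanded) mask contains the fixation centroid.

    The centroid is rounded to the nearest pixel. Off-image fixations and
    fixations in unannotated territory return ``{B}``.
    """
    col = int(round(x))
    row = int(round(y))
    if not (0 <= col < annotation.image_width and 0 <= row < annotation.image_height):
        return frozenset({BACKGROUND})
    hits = {sym for sym, m in annotation.masks.items() if m[row, col]}
    return frozenset(hits) if hits else frozenset({BACKGROUND})


# ---------------------------------------------------------------------------
# HMM-derived AOIs


class _HistoryMonitor(ConvergenceMonitor):
    """Convergence monitor that keeps the full log-likelihood history
    (the stock monitor keeps a 2-deep deque)."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: list[float] = []

    def report(self, log_prob: float) -> None:
        self.full_history.append(log_prob)
        super().report(log_prob)


@dataclass
class GazeHMM:
    """A fitted Gaussian-emission hidden Markov model over gaze positions.

    States are spatial clusters; ``means`` are the cluster centres in
    original-image pixels, ``transition_matrix`` the row-stochastic state
    transitions, and ``log_likelihood`` the training log-likelihood of the
    selected model. ``loglik_history`` records the EM trajectory.
    """

    n_states: int
    means: np.ndarray
    covariances: np.ndarray
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    log_likelihood: float
    bic: float
    loglik_history: list[float] = field(default_factory=list)
    degenerate: bool = False


def _fit_single(points: np.ndarray, k: int, seed: int, n_iter: int, tol: float):
    model = GaussianHMM(
        n_components=k,
        covariance_type="full",
        n_iter=n_iter,
        tol=tol,
        random_state=seed,
        min_covar=1e-3,
    )
    model.monitor_ = _HistoryMonitor(model.tol, model.n_iter, model.verbose)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(points)
    return model


def fit_gaze_hmm(
    points: np.ndarray,
    k_range: range | list[int] = range(2, 7),
    seed: int = 0,
    n_restarts: int = 5,
    n_iter: int = 500,
    tol: float = 1e-4,
) -> tuple[GazeHMM, np.ndarray]:
    """Cluster gaze positions with Gaussian HMMs, selecting the number of
    states by BIC.

    For each candidate ``k``, EM is run from ``n_restarts`` seeded k-means
    initialisations and the best restart (by log-likelihood) is kept; the
    winning ``k`` minimises BIC. State assignment is the Viterbi decoding of
    the selected model. Fully deterministic given ``seed``.

    Parameters
    ----------
    points
        ``(n, 2)`` array of gaze positions in image pixels, in temporal
        order (the HMM's transition structure is part of the model).
    k_range
        Candidate state counts; requires ``n >= 10 * max(k_range)``.

    Returns
    -------
    (model, assignment) where assignment is an ``(n,)`` integer state label
    per point.
    """
    points = np.asarray(points, dtype=float)
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(points)
    if n < 10 * max(k_range):
        raise ValueError(
            f"need at least 10 x max(k_range) = {10 * max(k_range)} points, got {n}"
        )

    # Degenerate input: all points (numerically) identical. EM on such data
    # is ill-posed; return a single-state model directly.
    if np.ptp(points, axis=0).max() < 1e-9:
        warnings.warn("all gaze points identical; returning a single-state model")
        model = GazeHMM(
            n_states=1,
            means=points[:1].copy(),
            covariances=np.eye(2)[None] * 1e-3,
            transition_matrix=np.ones((1, 1)),
            initial_distribution=np.ones(1),
            log_likelihood=0.0,
            bic=np.inf,
            degenerate=True,
        )
        return model, np.zeros(n, dtype=int)

    best_model = None
    best_bic = np.inf
    for k in k_range:
        best_for_k = None
        best_ll = -np.inf
        for r in range(n_restarts):
            try:
                m = _fit_single(points, k, seed * 1009 + 97 * k + r, n_iter, tol)
                ll = float(m.score(points))
            except (ValueError, np.linalg.LinAlgError):
                continue
            if ll > best_ll:
                best_ll = ll
                best_for_k = m
        if best_for_k is None:
            continue
        bic = float(best_for_k.bic(points))
        if bic < best_bic:
            best_bic = bic
            best_model = best_for_k
    if best_model is None:
        raise RuntimeError("no HMM fit succeeded for any k in k_range")

    assignment = best_model.predict(points)
    fitted = GazeHMM(
        n_states=best_model.n_components,
        means=best_model.means_.copy(),
        covariances=best_model.covars_.copy(),
        transition_matrix=best_model.transmat_.copy(),
        initial_distribution=best_model.startprob_.copy(),
        log_likelihood=float(best_model.score(points)),
        bic=best_bic,
        loglik_history=list(best_model.monitor_.full_history),
    )
    return fitted, assignment


def clusters_to_aoi_report(
    model: GazeHMM, annotation: AOIAnnotation
) -> dict:
    """Attribute each HMM state to the anatomical landmark whose expanded
    mask contains its mean, and report landmark coverage.

    Returns a dict with ``state_labels`` (per-state AOI symbol, B when the
    mean falls outside every mask or off-image), ``covered`` (per-landmark
    presence flags) and ``all_four_covered``.
    """
    if not annotation.expanded:
        annotation = expand_annotation(annotation)
    state_labels = []
    for mean in model.means:
        hits = label_fixation(mean[0], mean[1], annotation)
        anatomical = sorted(hits - {BACKGROUND})
        state_labels.append(anatomical[0] if anatomical else BACKGROUND)
    covered = {sym: sym in state_labels for sym in ANATOMICAL_LABELS}
    return {
        "state_labels": state_labels,
        "covered": covered,
        "all_four_covered": all(covered.values()),
    }
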