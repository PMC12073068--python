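"""Search-pattern discovery: edit-distance clustering of fixation strings
with Affinity Propagation.

Run-collapsed AOI pattern strings are compared by Levenshtein distance and
clustered with Affinity Propagation (similarity = negative distance), which
picks an actual member string as the exemplar of each cluster — a readable
canonical search pattern. Clustering correct and incorrect responses
separately exposes the search behaviour characteristic of each group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .stats import TestResult, mann_whitney

__all__ = [
    "StringCluster",
    "ClusteringConfig",
    "levenshtein",
    "distance_matrix",
    "cluster_strings",
    "top_clusters",
    "compare_group_patterns",
]


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions + deletions + substitutions)."""
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, task="distance")["editDistance"])


def distance_matrix(strings: list[str]) -> np.ndarray:
    """Pairwise Levenshtein distances (symmetric, zero diagonal)."""
    n = len(strings)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = levenshtein(strings[i], strings[j])
    return d


@dataclass(frozen=True)
class ClusteringConfig:
    """Affinity Propagation settings.

    ``preference=None`` (AUTO) uses the median similarity, which lets the
    data choose the number of clusters. Damping 0.9 trades speed for
    stability of the message passing.
    """

    damping: float = 0.9
    preference: float | None = None
    max_iter: int = 1000
    convergence_iter: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 <= self.damping < 1.0):
            raise ValueError("damping must be in [0.5, 1)")
        if self.max_iter <= self.convergence_iter:
            raise ValueError("max_iter must exceed convergence_iter")


@dataclass
class StringCluster:
    """One Affinity Propagation cluster: the exemplar pattern string, its
    member response ids, and the cluster size. The exemplar is always a
    member of its own cluster."""

    exemplar: str
    members: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def cluster_strings(
    strings: list[str],
    response_ids: list[str] | None = None,
    config: ClusteringConfig = ClusteringConfig(),
) -> tuple[list[StringCluster], bool]:
    """Cluster pattern strings by Affinity Propagation on negative
    Levenshtein distance.

    Every input is assigned to exactly one exemplar; the clusters partition
    the input. Deterministic given ``config.seed``. Returns the clusters
    and a ``converged`` flag; on non-convergence a best-effort assignment
    to the nearest medoid is returned with the flag set False.
    """
    n = len(strings)
    if n < 2:
        raise ValueError("need at least 2 strings to cluster")
    if response_ids is None:
        response_ids = [str(i) for i in range(n)]
    sim = -distance_matrix(strings)
    pref = config.preference if config.preference is not None else float(np.median(sim))
    ap = AffinityPropagation(
        affinity="precomputed",
        damping=config.damping,
        preference=pref,
        max_iter=config.max_iter,
        convergence_iter=config.convergence_iter,
        random_state=config.seed,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ap.fit(sim)
        except ConvergenceWarning:
            converged = False
    centres = getattr(ap, "cluster_centers_indices_", None)
    if not converged or centres is None or len(centres) == 0:
        # best-effort fallback: single cluster around the medoid
        warnings.warn("Affinity Propagation did not converge; falling back to medoid")
        medoid = int(np.argmax(sim.sum(axis=1)))
        return (
            [StringCluster(exemplar=strings[medoid], members=list(response_ids))],
            False,
        )
    # Merge clusters whose exemplars are the same string: duplicated inputs
    # routinely yield several AP exemplars that are textually identical, and
    # a search pattern should be reported once with its total support.
    clusters: dict[str, StringCluster] = {}
    for i, lab in enumerate(ap.labels_):
        exemplar = strings[int(ap.cluster_centers_indices_[lab])]
        clusters.setdefault(exemplar, StringCluster(exemplar=exemplar)).members.append(
            response_ids[i]
        )
    return list(clusters.values()), converged


def top_clusters(clusters: list[StringCluster], coverage: float = 0.75) -> list[StringCluster]:
    """Largest clusters covering at least ``coverage`` of the responses.

    Clusters are ordered by size descending (ties by exemplar
    lexicographically); the shortest prefix whose member total reaches
    ``coverage * n`` is returned.
    """
    if not (0 < coverage <= 1):
        raise ValueError("coverage must be in (0, 1]")
    ordered = sorted(clusters, key=lambda c: (-c.size, c.exemplar))
    total = sum(c.size for c in ordered)
    need = coverage * total
    out: list[StringCluster] = []
    acc = 0
    for c in ordered:
        out.append(c)
        acc += c.size
        if acc >= need:
            break
    return out


def compare_group_patterns(
    correct_strings: list[str],
    incorrect_strings: list[str],
    config: ClusteringConfig = ClusteringConfig(),
    coverage: float = 0.75,
) -> dict:
    """Cluster the correct and incorrect response groups separately and
    compare their search patterns.

    Returns per-group cluster lists (full and coverage-trimmed) and a
    Mann-Whitney comparison of exemplar string lengths between the groups
    (skipped with ``length_test=None`` when either group has fewer than
    two clusters or strings).
    """
    if not correct_strings or not incorrect_strings:
        raise ValueError("both groups must be non-empty")
    report: dict = {}
    for name, group in (("correct", correct_strings), ("incorrect", incorrect_strings)):
        if len(group) < 2:
            clusters = [StringCluster(exemplar=group[0], members=["0"])]
            converged = True
        else:
            clusters, converged = cluster_strings(group, config=config)
        report[name] = {
            "clusters": sorted(clusters, key=lambda c: (-c.size, c.exemplar)),
            "top": top_clusters(clusters, coverage=coverage),
            "converged": converged,
        }
    len_c = [len(c.exemplar) for c in report["correct"]["clusters"]]
    len_i = [len(c.exemplar) for c in report["incorrect"]["clusters"]]
    if len(len_c) >= 2 and len(len_i) >= 2:
        report["length_test"] = mann_whitney(len_c, len_i)
    else:
        report["length_test"] = None
    return report
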