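"""Fixation strings: resolving ambiguous AOI labels and collapsing runs.

Because expanded AOI annotations may overlap, a single fixation can match
several AOIs. The sequence of candidate label sets is resolved to a single
label per fixation by a minimum-transition assignment: build a layered
directed acyclic graph with one layer per fixation and one vertex per
candidate label, connect adjacent layers completely with edge cost 1 when
the labels differ and 0 when they match (plus a zero-cost virtual source and
sink), and take a minimum-cost source-to-sink path. An ambiguous fixation
flanked by unambiguous ones is thereby pulled onto the flanking AOI.

The optimum is computed by a layer-wise dynamic program, which on this DAG
is exact. Ties are broken deterministically: prefer continuing the previous
fixation's label, then the fixed symbol priority M > D > S > I > B
(favouring continuity and macula-centrality).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .aoi import AOI_LABELS, BACKGROUND

__all__ = [
    "SYMBOL_PRIORITY",
    "LabelledFixation",
    "FixationString",
    "resolve_labels",
    "min_transition_cost",
    "collapse_runs",
]

#: Tie-break priority among AOI symbols (first wins).
SYMBOL_PRIORITY = ("M", "D", "S", "I", "B")


@dataclass(frozen=True)
class LabelledFixation:
    """A fixation together with the set of AOI labels its centroid matched.

    ``candidates`` is non-empty; it is ``{B}`` exactly when no anatomical
    annotation matched. ``duration`` (ms) and the centroid ride along for
    downstream metrics and may be omitted for pure string work.
    """

    candidates: frozenset[str]
    x: float = 0.0
    y: float = 0.0
    onset: float = 0.0
    duration: float = 0.0

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("candidate set must be non-empty")
        unknown = set(self.candidates) - set(AOI_LABELS)
        if unknown:
            raise ValueError(f"unknown AOI symbols {unknown}")


@dataclass(frozen=True)
class FixationString:
    """Resolved AOI sequence for one grading response.

    ``resolved`` has one symbol per fixation; ``pattern`` is the exported
    search pattern: background removed, adjacent duplicates merged.
    ``cost`` is the number of label transitions of the optimal assignment.
    """

    response_id: str
    resolved: tuple[str, ...]
    pattern: str
    cost: int


def _priority_key(symbol: str) -> int:
    return SYMBOL_PRIORITY.index(symbol)


def min_transition_cost(candidate_sets: Sequence[Iterable[str]]) -> int:
    """Minimum number of label changes over all per-fixation assignments
    consistent with the candidate sets. Zero for empty or single-fixation
    input."""
    cost, _ = _solve(candidate_sets)
    return cost


def _solve(candidate_sets: Sequence[Iterable[str]]) -> tuple[int, list[str]]:
    layers = [sorted(set(c), key=_priority_key) for c in candidate_sets]
    if not layers:
        return 0, []
    for i, layer in enumerate(layers):
        if not layer:
            raise ValueError(f"fixation {i} has an empty candidate set")

    # Backward DP: best[i][l] = min transitions from layer i to the end,
    # assigning label l at layer i.
    n = len(layers)
    best: list[dict[str, int]] = [dict() for _ in range(n)]
    for l in layers[-1]:
        best[-1][l] = 0
    for i in range(n - 2, -1, -1):
        nxt = best[i + 1]
        cheapest_next = min(nxt.values())
        for l in layers[i]:
            stay = nxt.get(l)
            best[i][l] = min(
                cheapest_next + 1,
                stay if stay is not None else cheapest_next + 1,
            )

    # Forward walk with deterministic tie-breaks: prefer the previous
    # label when it stays optimal, then the fixed symbol priority (the
    # layers are already priority-sorted, so the first optimum wins).
    resolved: list[str] = []
    total = min(best[0].values())
    prev: str | None = None
    remaining = total
    for i, layer in enumerate(layers):
        choice = None
        if prev is not None and prev in best[i]:
            if best[i][prev] + 0 == remaining:  # continuing costs no transition
                choice = prev
        if choice is None:
            for l in layer:
                step = 0 if (prev is None or l == prev) else 1
                if step + best[i][l] == remaining:
                    choice = l
                    remaining -= step
                    break
            assert choice is not None
        resolved.append(choice)
        prev = choice
    return total, resolved


def resolve_labels(
    fixations: Sequence[LabelledFixation],
    response_id: str = "",
    b_breaks_runs: bool = False,
) -> FixationString:
    """Resolve ambiguous fixation labels to a single AOI string via the
    minimum-transition layered DAG (see module docstring).

    Background fixations are ordinary vertices in the graph (transitions to
    and from B cost 1 like any other change) and are removed from the
    exported pattern afterwards; ``b_breaks_runs`` selects the strict
    collapsing policy where a B terminates a visit.
    """
    cost, resolved = _solve([f.candidates for f in fixations])
    pattern = collapse_runs(resolved, b_breaks_runs=b_breaks_runs)
    return FixationString(
        response_id=response_id,
        resolved=tuple(resolved),
        pattern=pattern,
        cost=cost,
    )


def collapse_runs(resolved: Sequence[str], b_breaks_runs: bool = False) -> str:
    """Collapse a resolved label sequence to a pattern string over
    {D, M, S, I}: merge adjacent duplicates and drop background symbols.

    With the default policy a B sandwiched between equal labels merges
    across (M,B,M -> "M"); with ``b_breaks_runs=True`` the B terminates the
    visit, which matters for visit counting, but the exported pattern is
    re-collapsed so it never carries adjacent duplicates — both policies
    yield "M" for M,B,M. Idempotent.
    """
    if b_breaks_runs:
        # collapse runs first (B breaks them), then drop B, then re-collapse
        # to honour the no-adjacent-duplicates invariant of patterns
        step = [s for s, _ in _runs(resolved)]
        step = [s for s in step if s != BACKGROUND]
        return "".join(s for s, _ in _runs(step))
    dropped = [s for s in resolved if s != BACKGROUND]
    return "".join(s for s, _ in _runs(dropped))


def _runs(seq: Sequence[str]) -> list[tuple[str, int]]:
    """Maximal runs of equal symbols as (symbol, length) pairs."""
    out: list[tuple[str, int]] = []
    for s in seq:
        if out and out[-1][0] == s:
            out[-1] = (s, out[-1][1] + 1)
        else:
            out.append((s, 1))
    return out
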