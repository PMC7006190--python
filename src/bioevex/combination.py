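"""Combination strategy: assemble final events by penalty minimization.

Given candidate events with supports s^(e) and the supports of the detected
triggers s^(t) and relations s^(r), the selected subset c minimizes

    penalty(c) = sum_{event in c} max(1 - alpha * s^(e), 0)
               + beta  * sum_{uncovered triggers}  max(s^(t), 0)
               + gamma * sum_{uncovered relations} max(s^(r), 0)

("support lacking" for chosen low-confidence events plus "support waste" for
confident triggers/relations left out of every chosen event; negative
supports generate no waste). An exact brute-force solver serves as a testing
oracle; production selection is a greedy best-improvement loop over
topologically ordered candidates (children before the events that nest
them), with a loop detector and modification assignment as post-steps.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .standoff import EventRecord, TriggerMention

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltyWeights",
    "BundleCandidate",
    "SupportBundle",
    "SelectionResult",
    "penalty_score",
    "select_events_bruteforce",
    "select_events_greedy",
    "topological_sort_candidates",
    "detect_and_discard_loops",
    "assign_modifications",
]

BRUTE_FORCE_GUARD = 20


@dataclass(frozen=True)
class PenaltyWeights:
    alpha: float = 0.5
    beta: float = 0.25
    gamma: float = 0.125

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("penalty weights must be non-negative")


@dataclass
class BundleCandidate:
    """Abstract candidate event as the selector sees it.

    ``trigger`` identifies the candidate's own trigger, ``relations`` the
    relation ids it consumes, and ``filler_triggers`` the triggers of nested
    sub-events it references (which become covered when the candidate is
    chosen, and which must already carry a chosen event for the candidate to
    be realizable).
    """

    cid: int
    trigger: int
    relations: frozenset[int]
    s_e: float
    filler_triggers: frozenset[int] = frozenset()


@dataclass
class SupportBundle:
    trigger_support: dict[int, float]
    relation_support: dict[int, float]
    candidates: list[BundleCandidate]

    def __post_init__(self) -> None:
        for cand in self.candidates:
            if cand.trigger not in self.trigger_support:
                raise KeyError(f"candidate {cand.cid}: trigger {cand.trigger} not in bundle")
            for rid in cand.relations:
                if rid not in self.relation_support:
                    raise KeyError(f"candidate {cand.cid}: relation {rid} not in bundle")


@dataclass
class SelectionResult:
    chosen: list[BundleCandidate]
    penalty: float


def penalty_score(
    chosen: list[BundleCandidate] | tuple[BundleCandidate, ...],
    bundle: SupportBundle,
    w: PenaltyWeights,
) -> float:
    known = {id(c) for c in bundle.candidates}
    covered_triggers: set[int] = set()
    covered_relations: set[int] = set()
    lacking = 0.0
    for cand in chosen:
        if id(cand) not in known:
            raise KeyError(f"candidate {cand.cid} not part of the bundle")
        lacking += max(1.0 - w.alpha * cand.s_e, 0.0)
        covered_triggers.add(cand.trigger)
        covered_triggers.update(cand.filler_triggers)
        covered_relations.update(cand.relations)
    waste_t = sum(
        max(s, 0.0) for t, s in bundle.trigger_support.items() if t not in covered_triggers
    )
    waste_r = sum(
        max(s, 0.0) for r, s in bundle.relation_support.items() if r not in covered_relations
    )
    return lacking + w.beta * waste_t + w.gamma * waste_r


def select_events_bruteforce(bundle: SupportBundle, w: PenaltyWeights) -> SelectionResult:
    """Exact argmin over all subsets of the candidate set (testing oracle).

    Ties break toward smaller subsets, then lexicographic candidate order.
    Refuses instances above ``BRUTE_FORCE_GUARD`` candidates.
    """
    C = bundle.candidates
    if len(C) > BRUTE_FORCE_GUARD:
        raise ValueError(f"brute force limited to |C| <= {BRUTE_FORCE_GUARD}, got {len(C)}")
    best: tuple[float, int, tuple[int, ...]] | None = None
    best_subset: tuple[BundleCandidate, ...] = ()
    for r in range(len(C) + 1):
        for subset in itertools.combinations(C, r):
            pen = penalty_score(list(subset), bundle, w)
            key = (pen, len(subset), tuple(c.cid for c in subset))
            if best is None or key < best:
                best = key
                best_subset = subset
    assert best is not None
    return SelectionResult(chosen=list(best_subset), penalty=best[0])


def select_events_greedy(
    bundle: SupportBundle,
    w: PenaltyWeights,
    require_children: bool = True,
) -> SelectionResult:
    """Greedy best-improvement approximation of the penalty argmin.

    Candidates are first ordered topologically (sub-event triggers before
    the candidates nesting them) so a child's support is available when its
    parents are considered. Starting from the empty set, the admissible
    candidate whose inclusion lowers the penalty most is added until no
    inclusion helps; with ``require_children`` a candidate is admissible
    only once every nested filler trigger already carries a chosen event.
    O(|C|^2) penalty evaluations.
    """
    order = topological_sort_candidates(bundle.candidates, bundle.relation_support)
    chosen: list[BundleCandidate] = []
    chosen_triggers: set[int] = set()
    current = penalty_score(chosen, bundle, w)
    remaining = list(order)
    tol = 1e-12
    while True:
        best_gain = -1.0
        best_idx = -1
        best_pen = current
        for idx, cand in enumerate(remaining):
            if require_children and not cand.filler_triggers <= chosen_triggers:
                continue
            pen = penalty_score(chosen + [cand], bundle, w)
            gain = current - pen
            # admit strict improvements, and penalty-neutral candidates whose
            # own lacking term is zero (fully confident events cost nothing)
            eligible = gain > tol or (gain >= -tol and w.alpha * cand.s_e >= 1.0)
            if eligible and gain > best_gain + tol:
                best_gain, best_idx, best_pen = gain, idx, pen
        if best_idx < 0:
            break
        cand = remaining.pop(best_idx)
        chosen.append(cand)
        chosen_triggers.add(cand.trigger)
        current = best_pen
    assert abs(current - penalty_score(chosen, bundle, w)) < 1e-9
    return SelectionResult(chosen=chosen, penalty=current)


def topological_sort_candidates(
    candidates: list[BundleCandidate],
    relation_support: dict[int, float] | None = None,
) -> list[BundleCandidate]:
    """Order candidates children-first by their trigger nesting graph.

    Builds the trigger-level dependency graph (edge child -> parent when a
    parent candidate uses the child trigger as a filler). Cycles are broken
    by removing the edge backed by the lowest-support relation; without
    nesting the input order is preserved (stable).
    """
    triggers: list[int] = []
    seen: set[int] = set()
    for c in candidates:  # first-appearance order keeps the sort stable
        for t in (c.trigger, *sorted(c.filler_triggers)):
            if t not in seen:
                seen.add(t)
                triggers.append(t)
    # edge (child, parent) -> weakest relation support backing it
    edges: dict[tuple[int, int], float] = {}
    for cand in candidates:
        for child in cand.filler_triggers:
            rels = [
                relation_support.get(r, 0.0) if relation_support else 0.0
                for r in cand.relations
            ]
            weight = min(rels) if rels else 0.0
            key = (child, cand.trigger)
            edges[key] = max(edges.get(key, -np.inf), weight)

    def kahn(edge_set: dict[tuple[int, int], float]) -> list[int] | None:
        indeg = {t: 0 for t in triggers}
        for _, parent in edge_set:
            indeg[parent] += 1
        queue = [t for t in triggers if indeg[t] == 0]
        out: list[int] = []
        while queue:
            t = queue.pop(0)
            out.append(t)
            for (child, parent) in edge_set:
                if child == t:
                    indeg[parent] -= 1
                    if indeg[parent] == 0:
                        queue.append(parent)
        return out if len(out) == len(triggers) else None

    work = dict(edges)
    order = kahn(work)
    while order is None:
        drop = min(work, key=lambda k: (work[k], k))
        logger.debug("cyclic trigger nesting; dropping edge %s (support %.3f)", drop, work[drop])
        del work[drop]
        order = kahn(work)
    rank = {t: i for i, t in enumerate(order)}
    return sorted(candidates, key=lambda c: rank[c.trigger])


def detect_and_discard_loops(events: list[EventRecord]) -> list[EventRecord]:
    """Drop events that would close a cycle in the nested filler graph.

    Events are added one by one in the given (selection) order; an event is
    discarded when its inclusion would create a directed cycle over event
    references, including self-references. References to events that appear
    later in the list are honoured (edges persist from the moment the
    referencing event is accepted).
    """
    accepted: list[EventRecord] = []
    edges: dict[int, set[int]] = {}

    def reaches(src: int, dst: int, seen: set[int]) -> bool:
        if src == dst:
            return True
        if src in seen:
            return False
        seen.add(src)
        return any(reaches(nxt, dst, seen) for nxt in edges.get(src, ()))

    for ev in events:
        targets = [id(f) for _, f in ev.arguments if isinstance(f, EventRecord)]
        if any(reaches(t, id(ev), set()) for t in targets):
            logger.debug("discarding event %s: inclusion would create a loop", ev.id)
            continue
        accepted.append(ev)
        edges.setdefault(id(ev), set()).update(targets)
    return accepted


MOD_CLASSES = ("Negation", "Speculation", None)


def assign_modifications(
    events: list[EventRecord],
    logp_mods: list[np.ndarray] | None = None,
) -> list[EventRecord]:
    """Set each event's modification to the argmax of its p^(m).

    p^(m) orders classes (Negation, Speculation, None); ties that include
    None resolve to None. Events without a modification vector stay None.
    """
    for i, ev in enumerate(events):
        pm = logp_mods[i] if logp_mods is not None else (
            np.asarray(ev.logp_mod) if ev.logp_mod is not None else None
        )
        if pm is None:
            ev.modification = None
            continue
        best = float(np.max(pm))
        if pm[2] >= best - 1e-12:
            ev.modification = None
        else:
            ev.modification = MOD_CLASSES[int(np.argmax(pm))]
    return events
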