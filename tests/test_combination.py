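"""Penalty arithmetic, selection oracle vs greedy, loops, modifications."""

import math

import numpy as np
import pytest

from bioevex.combination import (
    BundleCandidate,
    PenaltyWeights,
    SupportBundle,
    assign_modifications,
    detect_and_discard_loops,
    penalty_score,
    select_events_bruteforce,
    select_events_greedy,
    topological_sort_candidates,
)
from bioevex.standoff import EventRecord, TriggerMention

W = PenaltyWeights(0.5, 0.25, 0.125)


def bundle_two_item():
    """One strong candidate event plus leftover trigger/relation supports."""
    return SupportBundle(
        trigger_support={0: 1.2, 1: 0.5},
        relation_support={0: 0.8, 1: 0.4},
        candidates=[BundleCandidate(cid=0, trigger=0, relations=frozenset({0}), s_e=3.0)],
    )


class TestPenaltyScore:
    def test_empty_selection_no_positive_supports(self):
        bundle = SupportBundle(trigger_support={0: -1.0}, relation_support={0: -0.5},
                               candidates=[])
        assert penalty_score([], bundle, W) == 0.0

    def test_hand_computed_chosen_event(self):
        bundle = bundle_two_item()
        pen = penalty_score(bundle.candidates, bundle, W)
        # max(1 - 0.5*3, 0) + 0.25*0.5 + 0.125*0.4
        assert pen == pytest.approx(0.175, abs=1e-12)

    def test_hand_computed_empty_selection(self):
        bundle = bundle_two_item()
        pen = penalty_score([], bundle, W)
        # 0.25*(1.2+0.5) + 0.125*(0.8+0.4)
        assert pen == pytest.approx(0.575, abs=1e-12)

    def test_negative_supports_generate_no_waste(self):
        bundle = SupportBundle(trigger_support={0: -2.0, 1: 1.0},
                               relation_support={0: -3.0}, candidates=[])
        assert penalty_score([], bundle, W) == pytest.approx(0.25 * 1.0)

    def test_unknown_candidate_rejected(self):
        bundle = bundle_two_item()
        alien = BundleCandidate(cid=9, trigger=0, relations=frozenset(), s_e=0.0)
        with pytest.raises(KeyError):
            penalty_score([alien], bundle, W)


class TestBruteForce:
    def test_empty_candidate_set_waste_only(self):
        bundle = SupportBundle(trigger_support={0: 2.0}, relation_support={},
                               candidates=[])
        res = select_events_bruteforce(bundle, W)
        assert res.chosen == [] and res.penalty == pytest.approx(0.5)

    def test_prefers_choosing_the_strong_event(self):
        bundle = bundle_two_item()
        res = select_events_bruteforce(bundle, W)
        assert [c.cid for c in res.chosen] == [0]
        assert res.penalty == pytest.approx(0.175)

    def test_all_negative_supports_empty_optimal(self):
        bundle = SupportBundle(
            trigger_support={0: -1.0}, relation_support={0: -1.0},
            candidates=[BundleCandidate(cid=0, trigger=0, relations=frozenset({0}),
                                        s_e=-5.0)],
        )
        res = select_events_bruteforce(bundle, W)
        assert res.chosen == [] and res.penalty == 0.0

    def test_guard_refuses_large_instances(self):
        cands = [BundleCandidate(cid=i, trigger=0, relations=frozenset(), s_e=0.0)
                 for i in range(21)]
        bundle = SupportBundle(trigger_support={0: 0.0}, relation_support={},
                               candidates=cands)
        with pytest.raises(ValueError, match="brute force"):
            select_events_bruteforce(bundle, W)


def random_instance(rng, n_cand=None):
    n_trig = int(rng.integers(1, 4))
    n_rel = int(rng.integers(0, 6))
    triggers = {i: float(rng.normal(0, 2)) for i in range(n_trig)}
    relations = {i: float(rng.normal(0, 2)) for i in range(n_rel)}
    n_cand = int(rng.integers(0, 9)) if n_cand is None else n_cand
    cands = []
    for c in range(n_cand):
        rel_ids = frozenset(
            int(i) for i in rng.choice(n_rel, size=rng.integers(0, n_rel + 1),
                                       replace=False)
        ) if n_rel else frozenset()
        cands.append(BundleCandidate(
            cid=c, trigger=int(rng.integers(0, n_trig)), relations=rel_ids,
            s_e=float(rng.normal(0, 2)),
        ))
    return SupportBundle(trigger_support=triggers, relation_support=relations,
                         candidates=cands)


class TestGreedyVsOracle:
    def test_greedy_matches_oracle_on_hand_instance(self):
        bundle = bundle_two_item()
        greedy = select_events_greedy(bundle, W)
        brute = select_events_bruteforce(bundle, W)
        assert greedy.penalty == pytest.approx(brute.penalty)

    def test_single_strongly_supported_candidate_chosen(self):
        bundle = SupportBundle(
            trigger_support={0: -1.0}, relation_support={},
            candidates=[BundleCandidate(cid=0, trigger=0, relations=frozenset(),
                                        s_e=5.0)],  # 1 - 0.5*5 < 0
        )
        res = select_events_greedy(bundle, W)
        assert [c.cid for c in res.chosen] == [0] and res.penalty == 0.0

    def test_oracle_never_worse_than_greedy_on_random_instances(self):
        rng = np.random.default_rng(1234)
        agree = 0
        n = 150
        for _ in range(n):
            bundle = random_instance(rng)
            greedy = select_events_greedy(bundle, W, require_children=False)
            brute = select_events_bruteforce(bundle, W)
            assert brute.penalty <= greedy.penalty + 1e-9
            assert greedy.penalty == pytest.approx(
                penalty_score(greedy.chosen, bundle, W))
            if abs(brute.penalty - greedy.penalty) < 1e-9:
                agree += 1
        assert agree / n > 0.8  # greedy solves the large majority exactly

    def test_enlarging_candidate_set_never_raises_oracle_penalty(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            bundle = random_instance(rng, n_cand=6)
            smaller = SupportBundle(bundle.trigger_support, bundle.relation_support,
                                    bundle.candidates[:3])
            pen_small = select_events_bruteforce(smaller, W).penalty
            pen_full = select_events_bruteforce(bundle, W).penalty
            assert pen_full <= pen_small + 1e-12


class TestTopologicalSort:
    def c(self, cid, trigger, fillers=(), rels=()):
        return BundleCandidate(cid=cid, trigger=trigger,
                               relations=frozenset(rels),
                               filler_triggers=frozenset(fillers), s_e=0.0)

    def test_children_precede_parents(self):
        cands = [self.c(0, trigger=0, fillers=[1]), self.c(1, trigger=1)]
        ordered = topological_sort_candidates(cands)
        assert [c.cid for c in ordered] == [1, 0]

    def test_no_nesting_preserves_input_order(self):
        cands = [self.c(0, 2), self.c(1, 0), self.c(2, 1)]
        assert [c.cid for c in topological_sort_candidates(cands)] == [0, 1, 2]

    def test_mutual_reference_cycle_broken_by_weakest_edge(self):
        cands = [
            self.c(0, trigger=0, fillers=[1], rels=[0]),
            self.c(1, trigger=1, fillers=[0], rels=[1]),
        ]
        ordered = topological_sort_candidates(cands, {0: 0.9, 1: 0.1})
        # edge backed by relation support 0.1 is dropped: trigger 1 -> 0 edge
        # remains, so trigger-1 candidate comes first
        assert [c.cid for c in ordered] == [1, 0]


def make_event(name, fillers=()):
    trig = TriggerMention(id=None, event_type="Regulation", char_start=0, char_end=1,
                          covered_text=name, token_start=0, token_end=1)
    return EventRecord(id=name, trigger=trig,
                       arguments=[("Cause", f) for f in fillers])


class TestLoopDetector:
    def test_mutual_pair_drops_second(self):
        e1 = make_event("E1")
        e2 = make_event("E2", fillers=[e1])
        e1.arguments.append(("Cause", e2))
        kept = detect_and_discard_loops([e1, e2])
        assert kept == [e1]

    def test_chain_kept(self):
        e3 = make_event("E3")
        e2 = make_event("E2", fillers=[e3])
        e1 = make_event("E1", fillers=[e2])
        assert detect_and_discard_loops([e3, e2, e1]) == [e3, e2, e1]

    def test_self_reference_dropped(self):
        e1 = make_event("E1")
        e1.arguments.append(("Cause", e1))
        assert detect_and_discard_loops([e1]) == []

    def test_random_injected_cycles_yield_acyclic_output(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(2, 7))
            events = [make_event(f"E{i}") for i in range(n)]
            for i in range(n):
                for j in range(n):
                    if i != j and rng.random() < 0.4:
                        events[i].arguments.append(("Cause", events[j]))
            kept = detect_and_discard_loops(events)
            # verify acyclicity of the kept set
            kept_ids = {id(e) for e in kept}
            seen = set()

            def dfs(ev, stack):
                assert id(ev) not in stack, "cycle survived the detector"
                stack = stack | {id(ev)}
                for _, f in ev.arguments:
                    if isinstance(f, EventRecord) and id(f) in kept_ids:
                        dfs(f, stack)

            for ev in kept:
                dfs(ev, frozenset())


class TestModifications:
    def ev(self):
        return make_event("E1")

    def test_argmax_negation(self):
        events = assign_modifications([self.ev()],
                                      [np.log(np.array([0.7, 0.2, 0.1]))])
        assert events[0].modification == "Negation"

    def test_uniform_ties_to_none(self):
        events = assign_modifications([self.ev()],
                                      [np.log(np.array([1 / 3, 1 / 3, 1 / 3]))])
        assert events[0].modification is None

    def test_empty_list(self):
        assert assign_modifications([]) == []
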