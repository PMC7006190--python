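"""Corpus scoring: approximate span / recursive event matching and errors.

A predicted event counts as a true positive only when its trigger and its
full argument structure are correct. Under the approximate criteria a
predicted trigger span may deviate from gold by up to one token on each
side (same event type required), and event-valued arguments are compared
recursively under the same relaxation; ``strict=True`` demands exact spans.
The error decomposition assigns each unmatched prediction or missed gold
event to exactly one of five categories (wrong trigger label, wrong trigger
span, wrong arguments, redundant arguments, other).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .standoff import Document, EntityMention, EventRecord, Token, TriggerMention

__all__ = [
    "ScoreReport",
    "ErrorBreakdown",
    "approximate_span_match",
    "event_match",
    "score_corpus",
    "classify_errors",
]


@dataclass
class TypeScore:
    tp: int = 0
    n_gold: int = 0
    n_pred: int = 0

    @property
    def recall(self) -> float:
        return self.tp / self.n_gold if self.n_gold else 0.0

    @property
    def precision(self) -> float:
        return self.tp / self.n_pred if self.n_pred else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


@dataclass
class ScoreReport:
    overall: TypeScore
    per_type: dict[str, TypeScore] = field(default_factory=dict)

    @property
    def recall(self) -> float:
        return self.overall.recall

    @property
    def precision(self) -> float:
        return self.overall.precision

    @property
    def f1(self) -> float:
        return self.overall.f1


ERROR_CATEGORIES = (
    "wrong_trigger_label",
    "wrong_trigger_span",
    "wrong_arguments",
    "redundant_arguments",
    "other",
)


@dataclass
class ErrorBreakdown:
    counts: dict[str, int]
    n_gold: int
    n_spurious: int

    @property
    def fractions(self) -> dict[str, float]:
        denom = self.n_gold + self.n_spurious
        return {k: (v / denom if denom else 0.0) for k, v in self.counts.items()}


def _extended_span(trig: TriggerMention, tokens: list[Token]) -> tuple[int, int]:
    """Gold span extended by one token on each side (character offsets)."""
    idx = [
        i for i, t in enumerate(tokens)
        if t.char_end > trig.char_start and t.char_start < trig.char_end
    ]
    if not idx:
        return trig.char_start, trig.char_end
    lo = tokens[idx[0] - 1].char_start if idx[0] > 0 else trig.char_start
    hi = tokens[idx[-1] + 1].char_end if idx[-1] + 1 < len(tokens) else trig.char_end
    return min(lo, trig.char_start), max(hi, trig.char_end)


def approximate_span_match(
    gold: TriggerMention,
    pred: TriggerMention,
    tokens: list[Token],
    strict: bool = False,
) -> bool:
    """Pred span within the gold span extended by one token per side."""
    if strict:
        return (pred.char_start, pred.char_end) == (gold.char_start, gold.char_end)
    lo, hi = _extended_span(gold, tokens)
    return lo <= pred.char_start and pred.char_end <= hi and pred.char_start < pred.char_end


def event_match(
    gold: EventRecord,
    pred: EventRecord,
    tokens: list[Token],
    strict: bool = False,
) -> bool:
    """Approximate recursive matching of full event structures."""
    if gold.trigger.event_type != pred.trigger.event_type:
        return False
    if not approximate_span_match(gold.trigger, pred.trigger, tokens, strict):
        return False
    if len(gold.arguments) != len(pred.arguments):
        return False
    used = [False] * len(pred.arguments)
    for role_g, filler_g in gold.arguments:
        found = False
        for j, (role_p, filler_p) in enumerate(pred.arguments):
            if used[j] or role_p != role_g:
                continue
            if isinstance(filler_g, EntityMention) and isinstance(filler_p, EntityMention):
                ok = (
                    filler_g.entity_type == filler_p.entity_type
                    and (filler_g.char_start, filler_g.char_end)
                    == (filler_p.char_start, filler_p.char_end)
                )
            elif isinstance(filler_g, EventRecord) and isinstance(filler_p, EventRecord):
                ok = event_match(filler_g, filler_p, tokens, strict)
            else:
                ok = False
            if ok:
                used[j] = True
                found = True
                break
        if not found:
            return False
    return True


def _match_documents(
    gold_doc: Document, pred_doc: Document, strict: bool
) -> tuple[list[tuple[EventRecord, EventRecord]], list[EventRecord], list[EventRecord]]:
    """Greedy 1-1 matching; returns (matches, missed gold, spurious pred)."""
    matched_gold: set[int] = set()
    matches: list[tuple[EventRecord, EventRecord]] = []
    spurious: list[EventRecord] = []
    for pred in pred_doc.events:
        hit = None
        for gold in gold_doc.events:
            if id(gold) in matched_gold:
                continue
            if event_match(gold, pred, gold_doc.tokens, strict):
                hit = gold
                break
        if hit is None:
            spurious.append(pred)
        else:
            matched_gold.add(id(hit))
            matches.append((hit, pred))
    missed = [g for g in gold_doc.events if id(g) not in matched_gold]
    return matches, missed, spurious


def _paired(gold_docs: list[Document], pred_docs: list[Document]) -> list[tuple[Document, Document]]:
    preds = {d.doc_id: d for d in pred_docs}
    if set(preds) != {d.doc_id for d in gold_docs}:
        raise ValueError("gold and predicted corpora have misaligned document ids")
    return [(g, preds[g.doc_id]) for g in gold_docs]


def score_corpus(
    gold_docs: list[Document],
    pred_docs: list[Document],
    strict: bool = False,
) -> ScoreReport:
    overall = TypeScore()
    per_type: dict[str, TypeScore] = {}

    def bucket(etype: str) -> TypeScore:
        return per_type.setdefault(etype, TypeScore())

    for gold_doc, pred_doc in _paired(gold_docs, pred_docs):
        matches, missed, spurious = _match_documents(gold_doc, pred_doc, strict)
        overall.tp += len(matches)
        overall.n_gold += len(gold_doc.events)
        overall.n_pred += len(pred_doc.events)
        for g in gold_doc.events:
            bucket(g.trigger.event_type).n_gold += 1
        for p in pred_doc.events:
            bucket(p.trigger.event_type).n_pred += 1
        for g, _ in matches:
            bucket(g.trigger.event_type).tp += 1
    return ScoreReport(overall=overall, per_type=per_type)


def classify_errors(
    gold_docs: list[Document],
    pred_docs: list[Document],
    strict: bool = False,
) -> ErrorBreakdown:
    """Five-way decomposition of unmatched predictions and missed golds.

    Category precedence per errored event: trigger span error, then trigger
    label error, then redundant arguments, then wrong arguments, then other.
    A spurious prediction whose trigger overlaps no gold trigger is a span
    error (triggers that do not exist in the gold standard).
    """
    counts = {k: 0 for k in ERROR_CATEGORIES}
    n_gold = n_spurious = 0

    def trigger_status(trig: TriggerMention, others: list[TriggerMention], tokens) -> str:
        span_ok_same = any(
            o.event_type == trig.event_type and approximate_span_match(o, trig, tokens, strict)
            for o in others
        )
        span_ok_any = span_ok_same or any(
            approximate_span_match(o, trig, tokens, strict) for o in others
        )
        if not span_ok_any:
            return "span"
        return "ok" if span_ok_same else "label"

    for gold_doc, pred_doc in _paired(gold_docs, pred_docs):
        matches, missed, spurious = _match_documents(gold_doc, pred_doc, strict)
        n_gold += len(gold_doc.events)
        n_spurious += len(spurious)
        gold_triggers = [e.trigger for e in gold_doc.events]
        pred_triggers = [e.trigger for e in pred_doc.events]
        tokens = gold_doc.tokens

        for pred in spurious:
            status = trigger_status(pred.trigger, gold_triggers, tokens)
            if status == "span":
                counts["wrong_trigger_span"] += 1
            elif status == "label":
                counts["wrong_trigger_label"] += 1
            else:
                # trigger is fine; compare against gold events on that trigger
                cat = "other"
                for gold in gold_doc.events:
                    if gold.trigger.event_type != pred.trigger.event_type:
                        continue
                    if not approximate_span_match(gold.trigger, pred.trigger, tokens, strict):
                        continue
                    roles_g = sorted(r for r, _ in gold.arguments)
                    roles_p = sorted(r for r, _ in pred.arguments)
                    if len(roles_p) > len(roles_g) and all(r in roles_p for r in roles_g):
                        cat = "redundant_arguments"
                        break
                    cat = "wrong_arguments"
                counts[cat] += 1

        for gold in missed:
            status = trigger_status(gold.trigger, pred_triggers, tokens)
            if status == "span":
                counts["wrong_trigger_span"] += 1
            elif status == "label":
                counts["wrong_trigger_label"] += 1
            else:
                counts["wrong_arguments"] += 1

    return ErrorBreakdown(counts=counts, n_gold=n_gold, n_spurious=n_spurious)
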