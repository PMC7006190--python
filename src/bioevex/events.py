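"""Event evaluation: candidate enumeration, role sequences and scoring.

Candidate events are all schema-valid combinations of a trigger's outgoing
relations (role min/max constraints enforced, enumeration capped keeping the
highest-support relations first). A candidate is rendered as a per-token role
label sequence R (event_trigger / role name / none_type), embedded, and run
through a second BiLSTM whose final states feed two log-softmax heads: a
2-class validity vector p^(e) — the support is s^(e) = p^(e)_valid -
p^(e)_invalid — and a 3-class modification vector p^(m) over Negation,
Speculation, None.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .encoders import BiLSTMLayer, NetConfig, SentenceEncoding, Vocabulary
from .relations import RelationPrediction
from .schema import EventSchema
from .standoff import EntityMention, TriggerMention

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateEvent",
    "EventHead",
    "enumerate_candidate_events",
    "role_label_sequence",
    "score_candidates",
    "undersample_negatives",
]


@dataclass
class CandidateEvent:
    trigger: TriggerMention
    relations: tuple[RelationPrediction, ...]  # one per argument
    candidate_id: int = -1
    s_e: float = 0.0
    logp_valid: Tensor | None = None
    logp_mod: Tensor | None = None

    @property
    def args(self) -> list[tuple[str, object]]:
        return [(rel.label, rel.pair.target) for rel in self.relations]

    @property
    def filler_triggers(self) -> list[TriggerMention]:
        return [rel.pair.target for rel in self.relations
                if isinstance(rel.pair.target, TriggerMention)]

    def arg_key(self) -> frozenset[tuple[str, int, int]]:
        """Hashable (role, filler char span) set for gold matching."""
        out = []
        for role, filler in self.args:
            span = (filler.char_start, filler.char_end)
            out.append((role, span[0], span[1]))
        return frozenset(out)


def enumerate_candidate_events(
    triggers: list[TriggerMention],
    relations: list[RelationPrediction],
    schema: EventSchema,
    cap: int = 128,
) -> list[CandidateEvent]:
    """All schema-valid combinations of each trigger's outgoing relations.

    For every trigger, relations are grouped by role; each role contributes
    between min and max fillers (all subsets of that size range), and the
    cross product over roles yields the candidates. Relations whose role or
    filler category the schema rejects are ignored. At most ``cap``
    candidates per trigger are kept, preferring combinations built from
    high-support relations.
    """
    candidates: list[CandidateEvent] = []
    for trig in triggers:
        if not schema.is_event_type(trig.event_type):
            continue
        specs = schema.roles_for(trig.event_type)
        outgoing = [
            rel for rel in relations
            if rel.pair.source is trig
            and rel.label != "none"
            and schema.allows(trig.event_type, rel.label, rel.pair.target_category)
        ]
        by_role: dict[str, list[RelationPrediction]] = {}
        for rel in sorted(outgoing, key=lambda r: -r.support):
            by_role.setdefault(rel.label, []).append(rel)
        per_role_choices: list[list[tuple[RelationPrediction, ...]]] = []
        satisfiable = True
        for role, spec in specs.items():
            avail = by_role.get(role, [])
            if len(avail) < spec.min_count:
                satisfiable = False
                break
            choices: list[tuple[RelationPrediction, ...]] = []
            hi = min(spec.max_count, len(avail))
            for count in range(spec.min_count, hi + 1):
                choices.extend(itertools.combinations(avail, count))
            per_role_choices.append(choices)
        if not satisfiable:
            continue
        trig_cands: list[CandidateEvent] = []
        over_cap = False
        for combo in itertools.product(*per_role_choices):
            rels = tuple(rel for group in combo for rel in group)
            trig_cands.append(CandidateEvent(trigger=trig, relations=rels))
            if len(trig_cands) >= cap:
                over_cap = True
                break
        if over_cap:
            logger.warning(
                "candidate cap %d reached for trigger %r; enumeration truncated",
                cap, trig.covered_text or trig.event_type,
            )
        candidates.extend(trig_cands)
    for i, cand in enumerate(candidates):
        cand.candidate_id = i
    return candidates


def role_label_sequence(cand: CandidateEvent, n: int, sent_offset: int = 0) -> list[str]:
    """Per-token role labels R over a sentence of n tokens.

    Argument filler tokens carry the argument's role (for a nested argument,
    the sub-event trigger's tokens), trigger tokens carry ``event_trigger``
    (highest precedence), everything else ``none_type``. Spans are
    document-token indices shifted by ``sent_offset``.
    """
    labels = ["none_type"] * n

    def check(s: int, e: int) -> range:
        if not (0 <= s < e <= n):
            raise ValueError(f"participant span ({s}, {e}) outside sentence of {n} tokens")
        return range(s, e)

    for rel in cand.relations:
        s, e = rel.pair.span2  # sentence-local filler span
        for i in check(s, e):
            if labels[i] == "none_type":
                labels[i] = rel.label
    ts = cand.trigger.token_start - sent_offset
    te = cand.trigger.token_end - sent_offset
    for i in check(ts, te):
        labels[i] = "event_trigger"
    return labels


class EventHead:
    """Role embedding + second BiLSTM + validity and modification heads."""

    N_MOD = 3  # Negation, Speculation, None

    def __init__(self, vocab: Vocabulary, cfg: NetConfig, enc_dim: int, rng: np.random.Generator):
        self.vocab = vocab
        self.cfg = cfg
        n_roles = len(vocab.role_seq_labels)
        self.role_table = ag.Parameter(
            ag.xavier_uniform(rng, n_roles, cfg.role_dim, (n_roles, cfg.role_dim))
        )
        in_dim = enc_dim + cfg.entity_dim + cfg.trigger_label_dim + cfg.role_dim
        self.bilstm = BiLSTMLayer(in_dim, cfg.hidden, rng)
        out_dim = 2 * cfg.hidden
        self.W_valid = ag.Parameter(ag.xavier_uniform(rng, out_dim, 2, (2, out_dim)))
        self.b_valid = ag.Parameter(np.zeros(2))
        self.W_mod = ag.Parameter(ag.xavier_uniform(rng, out_dim, self.N_MOD, (self.N_MOD, out_dim)))
        self.b_mod = ag.Parameter(np.zeros(self.N_MOD))

    def parameters(self) -> list[Tensor]:
        return [self.role_table, self.W_valid, self.b_valid, self.W_mod, self.b_mod] \
            + self.bilstm.parameters()

    def evaluate(
        self,
        cand: CandidateEvent,
        enc: SentenceEncoding,
        T: list[Tensor],
        sent_offset: int = 0,
    ) -> tuple[Tensor, Tensor]:
        """Score one candidate: returns (p^(e) log-probs, p^(m) log-probs)."""
        n = len(enc)
        role_labels = role_label_sequence(cand, n, sent_offset)
        role_ids = [self.vocab.role_seq_labels.index(lbl) for lbl in role_labels]
        xs = [
            ag.concat([enc.H[i], enc.E[i], T[i], self.role_table.row(role_ids[i])])
            for i in range(n)
        ]
        fwd = self.bilstm.fwd.run(xs)
        bwd = self.bilstm.bwd.run(xs, reverse=True)
        h_last = ag.concat([fwd[-1], bwd[0]])
        p_e = ((self.W_valid @ h_last) + self.b_valid).log_softmax()
        p_m = ((self.W_mod @ h_last) + self.b_mod).log_softmax()
        return p_e, p_m


def score_candidates(
    heads: list[EventHead],
    encs: list[SentenceEncoding],
    Ts: list[list[Tensor]],
    candidates: list[CandidateEvent],
    sent_offset: int = 0,
) -> None:
    """Attach ensemble-averaged p^(e), p^(m) and s^(e) to each candidate."""
    for cand in candidates:
        pes, pms = [], []
        for m, head in enumerate(heads):
            p_e, p_m = head.evaluate(cand, encs[m], Ts[m], sent_offset)
            pes.append(p_e)
            pms.append(p_m)
        p_e = pes[0] if len(pes) == 1 else ag.add_n(pes).scale(1.0 / len(pes))
        p_m = pms[0] if len(pms) == 1 else ag.add_n(pms).scale(1.0 / len(pms))
        cand.logp_valid = p_e
        cand.logp_mod = p_m
        cand.s_e = float(p_e.data[0] - p_e.data[1])


def undersample_negatives(
    candidates: list[CandidateEvent],
    labels: list[int],
    rng: np.random.Generator,
) -> list[int]:
    """Indices of the training subset balancing positives and negatives.

    All positives are kept; negatives are sampled down to the positive count
    (at least one negative is kept whenever any exist). Deterministic for a
    given generator state.
    """
    pos = [i for i, y in enumerate(labels) if y == 1]
    neg = [i for i, y in enumerate(labels) if y == 0]
    n_keep = max(len(pos), 1) if neg else 0
    if len(neg) > n_keep:
        kept_neg = sorted(rng.choice(len(neg), size=n_keep, replace=False).tolist())
        neg = [neg[i] for i in kept_neg]
    return sorted(pos + neg)
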