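"""Relation classification over trigger->(trigger|entity) candidate pairs.

Each ordered pair is described by pooled feature slices of the shared
encoding: src/dst are adaptive max poolings of [H, T, E] over the two
argument spans, mid is a convolution + max pooling over the between-segment
(a learned adjacency vector when the spans touch), and a clipped token
distance is embedded as d_v. A two-layer scorer with log-softmax yields
p^(r); the assigned class's margin over none is the relation's support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .encoders import NetConfig, SentenceEncoding, Vocabulary
from .schema import EventSchema
from .standoff import EntityMention, TriggerMention

__all__ = [
    "CandidatePair",
    "RelationHead",
    "RelationPrediction",
    "generate_candidate_pairs",
    "classify_pairs",
]


@dataclass(frozen=True)
class CandidatePair:
    """Ordered candidate: source trigger -> target trigger or entity.

    Token spans are sentence-local [start, end) ranges; ``distance`` is the
    token gap between the spans in text order (start of the later span minus
    end of the earlier), and ``reversed_order`` flags pairs whose target
    precedes the source in the text.
    """

    source: TriggerMention
    target: object  # TriggerMention | EntityMention
    span1: tuple[int, int]
    span2: tuple[int, int]

    @property
    def reversed_order(self) -> bool:
        return self.span2[0] < self.span1[0]

    @property
    def distance(self) -> int:
        (s1, e1), (s2, e2) = sorted([self.span1, self.span2])
        return max(0, s2 - e1)

    @property
    def target_category(self) -> str:
        if isinstance(self.target, EntityMention):
            return self.target.entity_type
        return self.target.event_type


@dataclass
class RelationPrediction:
    pair: CandidatePair
    label: str  # role name or "none"
    logp: Tensor
    support: float
    relation_id: int = -1


def generate_candidate_pairs(
    triggers: list[TriggerMention],
    entities: list[EntityMention],
    sent_token_range: tuple[int, int],
    tokens,
) -> list[CandidatePair]:
    """All ordered trigger->(trigger|entity) pairs within one sentence.

    Self-pairs are excluded; trigger-trigger pairs are generated in both
    directions since nesting is directional.
    """
    lo, hi = sent_token_range
    pairs: list[CandidatePair] = []

    def local_span(char_start: int, char_end: int) -> tuple[int, int] | None:
        idx = [
            i - lo
            for i in range(lo, hi)
            if tokens[i].char_end > char_start and tokens[i].char_start < char_end
        ]
        if not idx:
            return None
        return idx[0], idx[-1] + 1

    ent_spans = {id(e): local_span(e.char_start, e.char_end) for e in entities}
    for src in triggers:
        span1 = (src.token_start - lo, src.token_end - lo)
        for tgt in triggers:
            if tgt is src:
                continue
            pairs.append(
                CandidatePair(src, tgt, span1, (tgt.token_start - lo, tgt.token_end - lo))
            )
        for ent in entities:
            span2 = ent_spans[id(ent)]
            if span2 is None:
                continue
            pairs.append(CandidatePair(src, ent, span1, span2))
    return pairs


class RelationHead:
    """Pair feature builder and two-layer relation scorer."""

    def __init__(self, vocab: Vocabulary, cfg: NetConfig, enc_dim: int, rng: np.random.Generator):
        self.vocab = vocab
        self.cfg = cfg
        slice_dim = enc_dim + cfg.trigger_label_dim + cfg.entity_dim
        self.slice_dim = slice_dim
        mc, mk = cfg.mid_channels, cfg.mid_kernel
        self.mid_W = ag.Parameter(ag.xavier_uniform(rng, mk * slice_dim, mc, (mc, mk * slice_dim)))
        self.mid_b = ag.Parameter(np.zeros(mc))
        self.adjacency = ag.Parameter(ag.xavier_uniform(rng, 1, mc, (mc,)))
        self.dist_table = ag.Parameter(
            ag.xavier_uniform(rng, cfg.distance_clip + 1, cfg.distance_dim,
                              (cfg.distance_clip + 1, cfg.distance_dim))
        )
        n_classes = len(vocab.relation_labels)
        r_dim = 2 * slice_dim + mc + cfg.distance_dim + 1  # +1: direction flag
        hh = cfg.head_hidden
        self.W4 = ag.Parameter(ag.xavier_uniform(rng, r_dim, hh, (hh, r_dim)))
        self.b4 = ag.Parameter(np.zeros(hh))
        self.W5 = ag.Parameter(ag.xavier_uniform(rng, hh, n_classes, (n_classes, hh)))
        self.b5 = ag.Parameter(np.zeros(hh))  # added before W5: y = W5(f(W4 r + b4) + b5)

    def parameters(self) -> list[Tensor]:
        return [self.mid_W, self.mid_b, self.adjacency, self.dist_table,
                self.W4, self.b4, self.W5, self.b5]

    # -- features ----------------------------------------------------------

    def _slice_rows(self, enc: SentenceEncoding, T: list[Tensor], lo: int, hi: int) -> list[Tensor]:
        return [ag.concat([enc.H[i], T[i], enc.E[i]]) for i in range(lo, hi)]

    def pair_features(self, pair: CandidatePair, enc: SentenceEncoding, T: list[Tensor]) -> Tensor:
        n = len(enc)
        for s, e in (pair.span1, pair.span2):
            if not (0 <= s < e <= n):
                raise ValueError(f"pair span ({s}, {e}) outside sentence of {n} tokens")
        # slices taken in text order; a flag carries the original direction
        (ls, le), (rs, re) = sorted([pair.span1, pair.span2])
        src_rows = self._slice_rows(enc, T, *pair.span1)
        dst_rows = self._slice_rows(enc, T, *pair.span2)
        src_max = ag.stack(src_rows).max_over_rows()
        dst_max = ag.stack(dst_rows).max_over_rows()
        mid_lo, mid_hi = min(le, rs), max(le, rs)
        if mid_hi <= mid_lo:
            mid_max = self.adjacency
        else:
            rows = self._slice_rows(enc, T, mid_lo, mid_hi)
            while len(rows) < self.cfg.mid_kernel:  # pad short mid segments
                rows.append(ag.constant(np.zeros(self.slice_dim)))
            mid_max = ag.conv1d_rows(ag.stack(rows), self.mid_W, self.mid_b).leaky_relu().max_over_rows()
        d = min(pair.distance, self.cfg.distance_clip)
        d_v = self.dist_table.row(d)
        flag = ag.constant(np.asarray([1.0 if pair.reversed_order else 0.0]))
        return ag.concat([src_max, mid_max, dst_max, d_v, flag])

    def logp(self, features: Tensor) -> Tensor:
        hidden = ((self.W4 @ features) + self.b4).leaky_relu() + self.b5
        return (self.W5 @ hidden).log_softmax()


def classify_pairs(
    heads: list[RelationHead],
    encs: list[SentenceEncoding],
    Ts: list[list[Tensor]],
    pairs: list[CandidatePair],
    threshold_r: float,
    schema: EventSchema | None = None,
) -> list[RelationPrediction]:
    """Score pairs (ensemble-averaged) and apply the threshold rule.

    A non-none class m is assigned when p_m - p_none > threshold_r (ties at
    the argmax go to the lowest class index). With a schema, roles the
    source trigger's event type cannot take are reset to none before EE.
    """
    out: list[RelationPrediction] = []
    vocab = heads[0].vocab
    for pair in pairs:
        logps = [head.logp(head.pair_features(pair, encs[m], Ts[m])) for m, head in enumerate(heads)]
        comb = logps[0] if len(logps) == 1 else ag.add_n(logps).scale(1.0 / len(logps))
        p = comb.data
        m_star = 1 + int(np.argmax(p[1:]))
        margin = float(p[m_star] - p[0])
        label = vocab.relation_labels[m_star] if margin > threshold_r else "none"
        if (
            label != "none"
            and schema is not None
            and not schema.allows(pair.source.event_type, label, pair.target_category)
        ):
            label = "none"
        out.append(RelationPrediction(pair=pair, label=label, logp=comb, support=margin))
    for i, rel in enumerate(out):
        rel.relation_id = i
    return out
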