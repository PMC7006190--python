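"""Trigger recognition: greedy left-to-right BILOU labeling with feedback.

At token i the head scores x_i = [h_i, t_{i-1}] where t_{i-1} is the
embedding of the previously *assigned* label (a learned start vector at
i = 0). A label m != O is assigned when its log-probability margin over the
O class exceeds ``threshold_t``; the margin is the label's support value.
During training, scheduled sampling feeds the gold previous label with
probability eps = k / (k + exp(epoch / k)) and the model's own assignment
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .encoders import NetConfig, SentenceEncoding, Vocabulary
from .standoff import Token, TriggerMention, decode_bilou

__all__ = [
    "TriggerHead",
    "TriggerPrediction",
    "recognize_triggers",
    "scheduled_sampling_prob",
    "trigger_label_ids",
]


def scheduled_sampling_prob(epoch: int, k: float) -> float:
    """Inverse sigmoid decay eps = k / (k + exp(epoch / k))."""
    if k <= 0:
        raise ValueError(f"scheduled sampling constant k must be > 0, got {k}")
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    try:
        return k / (k + math.exp(epoch / k))
    except OverflowError:
        return 0.0


class TriggerHead:
    """Two linear layers over [h_i, t_{i-1}] plus the label embedding table.

    The embedding table has one extra row used as the learned
    start-of-sentence label vector t_0.
    """

    def __init__(self, vocab: Vocabulary, cfg: NetConfig, in_dim: int, rng: np.random.Generator):
        n_labels = len(vocab.trigger_labels)
        td, hh = cfg.trigger_label_dim, cfg.head_hidden
        self.vocab = vocab
        self.n_labels = n_labels
        x_dim = in_dim + td
        self.W2 = ag.Parameter(ag.xavier_uniform(rng, x_dim, hh, (hh, x_dim)))
        self.b2 = ag.Parameter(np.zeros(hh))
        self.W3 = ag.Parameter(ag.xavier_uniform(rng, hh, n_labels, (n_labels, hh)))
        self.b3 = ag.Parameter(np.zeros(hh))  # added before W3, matching y = W3(f(W2 x + b2) + b3)
        self.label_table = ag.Parameter(
            ag.xavier_uniform(rng, n_labels + 1, td, (n_labels + 1, td))
        )

    def parameters(self) -> list[Tensor]:
        return [self.W2, self.b2, self.W3, self.b3, self.label_table]

    def start_embedding(self) -> Tensor:
        return self.label_table.row(self.n_labels)

    def label_embedding(self, label_id: int) -> Tensor:
        return self.label_table.row(label_id)

    def logp(self, h_i: Tensor, t_prev: Tensor) -> Tensor:
        x = ag.concat([h_i, t_prev])
        hidden = ((self.W2 @ x) + self.b2).leaky_relu() + self.b3
        return ((self.W3 @ hidden)).log_softmax()


@dataclass
class TriggerPrediction:
    label_ids: list[int]
    labels: list[str]
    logp: list[Tensor]  # combined per-token log-probability vectors
    member_logp: list[list[Tensor]]  # per member, per token (for training loss)
    T: list[list[Tensor]]  # per member: trigger-label embedding sequence t_1..t_n
    margins: np.ndarray  # per-token margin of the assigned non-O label over O
    triggers: list[TriggerMention] = field(default_factory=list)


def recognize_triggers(
    heads: list[TriggerHead],
    encs: list[SentenceEncoding],
    tokens: list[Token],
    threshold_t: float,
    text: str | None = None,
    train: bool = False,
    gold_label_ids: list[int] | None = None,
    teacher_prob: float = 1.0,
    rng: np.random.Generator | None = None,
) -> TriggerPrediction:
    """Greedy left-to-right decode, optionally over an ensemble.

    With several (head, encoding) members the per-class log-probabilities are
    averaged before the threshold test; every member feeds its own embedding
    of the shared assigned (or sampled gold) label into its next step.
    """
    n = len(tokens)
    vocab = heads[0].vocab
    t_prev = [head.start_embedding() for head in heads]
    label_ids: list[int] = []
    combined: list[Tensor] = []
    member_logp: list[list[Tensor]] = [[] for _ in heads]
    T: list[list[Tensor]] = [[] for _ in heads]
    margins = np.zeros(n)

    for i in range(n):
        logps = [head.logp(encs[m].H[i], t_prev[m]) for m, head in enumerate(heads)]
        for m, lp in enumerate(logps):
            member_logp[m].append(lp)
        comb = logps[0] if len(logps) == 1 else ag.add_n(logps).scale(1.0 / len(logps))
        combined.append(comb)
        p = comb.data
        m_star = 1 + int(np.argmax(p[1:])) if len(p) > 1 else 0
        margin = p[m_star] - p[0]
        assigned = m_star if margin > threshold_t else 0
        margins[i] = margin if assigned != 0 else margin
        label_ids.append(assigned)
        if train and gold_label_ids is not None:
            feed = gold_label_ids[i] if (rng is None or rng.random() < teacher_prob) else assigned
        else:
            feed = assigned
        for m, head in enumerate(heads):
            emb = head.label_embedding(feed)
            t_prev[m] = emb
            T[m].append(emb)

    labels = [vocab.trigger_labels[i] for i in label_ids]
    triggers = decode_bilou(labels, tokens)
    out: list[TriggerMention] = []
    for trig in triggers:
        span_margins = margins[trig.token_start : trig.token_end]
        support = float(span_margins.mean())
        covered = text[trig.char_start : trig.char_end] if text is not None else trig.covered_text
        out.append(
            TriggerMention(
                id=None,
                event_type=trig.event_type,
                char_start=trig.char_start,
                char_end=trig.char_end,
                covered_text=covered,
                token_start=trig.token_start,
                token_end=trig.token_end,
                sentence_index=trig.sentence_index,
                support=support,
            )
        )
    return TriggerPrediction(
        label_ids=label_ids,
        labels=labels,
        logp=combined,
        member_logp=member_logp,
        T=T,
        margins=margins,
        triggers=out,
    )


def trigger_label_ids(labels: list[str], vocab: Vocabulary) -> list[int]:
    index = {lbl: i for i, lbl in enumerate(vocab.trigger_labels)}
    return [index[lbl] for lbl in labels]
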