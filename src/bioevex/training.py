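"""Joint training and prediction orchestration.

One shared encoder feeds the trigger (TR), relation (RC) and event (EE)
heads; the four NLL terms (triggers, relations, event validity, event
modification) are summed and back-propagated together, so all heads shape
the shared parameters. Training teacher-forces RC/EE on gold triggers and
relations while TR uses scheduled sampling; prediction runs the fully
predicted pipeline per sentence — encode, TR, RC, candidate enumeration, EE,
combination strategy, loop detection, modification assignment — optionally
over an ensemble whose per-class log-probabilities are averaged before any
support/threshold logic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .combination import (
    BundleCandidate,
    PenaltyWeights,
    SelectionResult,
    SupportBundle,
    assign_modifications,
    detect_and_discard_loops,
    select_events_greedy,
)
from .encoders import Encoder, NetConfig, SentenceEncoding, Vocabulary, entity_labels_for
from .events import (
    CandidateEvent,
    EventHead,
    enumerate_candidate_events,
    score_candidates,
    undersample_negatives,
)
from .relations import (
    CandidatePair,
    RelationHead,
    RelationPrediction,
    classify_pairs,
    generate_candidate_pairs,
)
from .schema import EventSchema
from .standoff import (
    Document,
    EntityMention,
    EventRecord,
    TriggerMention,
    encode_bilou,
)
from .triggers import (
    TriggerHead,
    recognize_triggers,
    scheduled_sampling_prob,
    trigger_label_ids,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "ModelBundle",
    "train",
    "predict_document",
    "predict_corpus",
    "ensemble_combine",
    "save_ensemble",
    "load_ensemble",
]

MODES = ("cs", "rule-single", "rule-all", "ee-probability", "zero-threshold")
MOD_TARGET = {"Negation": 0, "Speculation": 1, None: 2}


@dataclass
class TrainConfig:
    learning_rate: float = 0.007
    class_weight_ratio: float = 5.0  # positive:negative for TR and RC
    weight_decay: float = 0.0002
    batch_size: int = 16
    epochs: int = 100
    ensemble_size: int = 5
    seed: int = 0
    threshold_t: float = -2.0
    threshold_r: float = -2.0
    scheduled_k: float = 10.0
    alpha: float = 0.5
    beta: float = 0.25
    gamma: float = 0.125
    candidate_cap: int = 128
    mode: str = "cs"
    net: NetConfig = field(default_factory=NetConfig)

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def penalty_weights(self) -> PenaltyWeights:
        return PenaltyWeights(self.alpha, self.beta, self.gamma)

    @classmethod
    def from_dict(cls, raw: dict) -> "TrainConfig":
        raw = dict(raw)
        net = NetConfig(**raw.pop("net", {}))
        return cls(net=net, **raw)


class ModelBundle:
    """Shared encoder plus the three task heads of one ensemble member."""

    def __init__(self, vocab: Vocabulary, net: NetConfig, rng: np.random.Generator):
        self.vocab = vocab
        self.net = net
        self.encoder = Encoder(vocab, net, rng)
        enc_dim = self.encoder.out_dim
        self.trigger_head = TriggerHead(vocab, net, enc_dim, rng)
        self.relation_head = RelationHead(vocab, net, enc_dim, rng)
        self.event_head = EventHead(vocab, net, enc_dim, rng)

    def parameters(self) -> list[Tensor]:
        return (
            self.encoder.parameters()
            + self.trigger_head.parameters()
            + self.relation_head.parameters()
            + self.event_head.parameters()
        )


# ---------------------------------------------------------------------------
# Gold preprocessing
# ---------------------------------------------------------------------------


@dataclass
class SentenceExample:
    doc_id: str
    tokens: list  # document Token objects of this sentence
    ent_labels: list[str]
    gold_label_ids: list[int]
    triggers: list[TriggerMention]  # sentence-local token spans
    pairs: list[CandidatePair]
    pair_labels: list[int]
    candidates: list[CandidateEvent]
    cand_labels: list[int]
    cand_mods: list[int]


def _gold_relations(doc: Document) -> dict[tuple[int, int], str]:
    """(source trigger identity, filler identity) -> role, over gold events."""
    rels: dict[tuple[int, int], str] = {}
    for ev in doc.events:
        for role, filler in ev.arguments:
            tgt = filler.trigger if isinstance(filler, EventRecord) else filler
            rels.setdefault((id(ev.trigger), id(tgt)), role)
    return rels


def build_examples(docs: list[Document], vocab: Vocabulary, schema: EventSchema,
                   cap: int = 128) -> list[SentenceExample]:
    examples: list[SentenceExample] = []
    rel_index = {lbl: i for i, lbl in enumerate(vocab.relation_labels)}
    for doc in docs:
        gold_rels = _gold_relations(doc)
        gold_keys: dict[int, list[tuple[frozenset, int | None]]] = {}
        for ev in doc.events:
            key = frozenset(
                (role,
                 (f.trigger if isinstance(f, EventRecord) else f).char_start,
                 (f.trigger if isinstance(f, EventRecord) else f).char_end)
                for role, f in ev.arguments
            )
            gold_keys.setdefault(id(ev.trigger), []).append((key, MOD_TARGET[ev.modification]))
        for si in range(len(doc.sentences)):
            lo, hi = doc.sentence_token_range(si)
            tokens = doc.tokens[lo:hi]
            if not tokens:
                continue
            ent_labels = entity_labels_for(tokens, doc.entities)
            triggers = [
                replace(t, token_start=t.token_start - lo, token_end=t.token_end - lo)
                for t in doc.triggers
                if t.sentence_index == si
            ]
            # identity map from shifted copies back to the originals
            originals = [t for t in doc.triggers if t.sentence_index == si]
            local_of = {id(triggers[i]): originals[i] for i in range(len(triggers))}
            labels = encode_bilou(tokens, triggers)
            gold_ids = trigger_label_ids(labels, vocab)
            entities = [
                e for e in doc.entities
                if any(t.char_end > e.char_start and t.char_start < e.char_end for t in tokens)
            ]
            pairs = generate_candidate_pairs(triggers, entities, (0, len(tokens)), tokens)
            pair_labels = []
            for pair in pairs:
                src = local_of[id(pair.source)]
                tgt = pair.target
                if isinstance(tgt, TriggerMention):
                    tgt = local_of[id(tgt)]
                role = gold_rels.get((id(src), id(tgt)), "none")
                pair_labels.append(rel_index.get(role, 0))
            gold_rel_preds = [
                RelationPrediction(
                    pair=pair,
                    label=vocab.relation_labels[lbl],
                    logp=None,  # type: ignore[arg-type]
                    support=1.0,
                    relation_id=i,
                )
                for i, (pair, lbl) in enumerate(zip(pairs, pair_labels))
                if lbl != 0
            ]
            candidates = enumerate_candidate_events(triggers, gold_rel_preds, schema, cap=cap)
            cand_labels, cand_mods = [], []
            for cand in candidates:
                src = local_of[id(cand.trigger)]
                matches = [m for key, m in gold_keys.get(id(src), []) if key == cand.arg_key()]
                cand_labels.append(1 if matches else 0)
                cand_mods.append(matches[0] if matches else MOD_TARGET[None])
            examples.append(
                SentenceExample(
                    doc_id=doc.doc_id,
                    tokens=tokens,
                    ent_labels=ent_labels,
                    gold_label_ids=gold_ids,
                    triggers=triggers,
                    pairs=pairs,
                    pair_labels=pair_labels,
                    candidates=candidates,
                    cand_labels=cand_labels,
                    cand_mods=cand_mods,
                )
            )
    return examples


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def weighted_nll(logps: list[Tensor], targets: list[int], weights: list[float]) -> Tensor:
    """sum_i w_i * (-logp_i[y_i]) / n — class weights scale terms linearly."""
    terms = [lp.pick(y).scale(-w) for lp, y, w in zip(logps, targets, weights)]
    return ag.add_n(terms).scale(1.0 / len(terms))


def sentence_losses(
    model: ModelBundle,
    ex: SentenceExample,
    cfg: TrainConfig,
    epoch: int,
    rng: np.random.Generator,
) -> dict[str, Tensor | None]:
    """Forward pass of one sentence; returns the four loss Tensors."""
    enc = model.encoder.encode(ex.tokens, ex.ent_labels, train=True, rng=rng)
    eps = scheduled_sampling_prob(epoch, cfg.scheduled_k)
    tp = recognize_triggers(
        [model.trigger_head], [enc], ex.tokens, cfg.threshold_t,
        train=True, gold_label_ids=ex.gold_label_ids, teacher_prob=eps, rng=rng,
    )
    w = cfg.class_weight_ratio
    tr_loss = weighted_nll(
        tp.member_logp[0], ex.gold_label_ids,
        [w if y != 0 else 1.0 for y in ex.gold_label_ids],
    )
    T = tp.T[0]
    rc_loss = None
    if ex.pairs:
        logps = [
            model.relation_head.logp(model.relation_head.pair_features(p, enc, T))
            for p in ex.pairs
        ]
        rc_loss = weighted_nll(
            logps, ex.pair_labels, [w if y != 0 else 1.0 for y in ex.pair_labels]
        )
    ee_loss = mod_loss = None
    if ex.candidates:
        keep = undersample_negatives(ex.candidates, ex.cand_labels, rng)
        val_logps, val_targets, mod_logps, mod_targets = [], [], [], []
        for i in keep:
            p_e, p_m = model.event_head.evaluate(ex.candidates[i], enc, T)
            val_logps.append(p_e)
            val_targets.append(0 if ex.cand_labels[i] == 1 else 1)
            if ex.cand_labels[i] == 1:
                mod_logps.append(p_m)
                mod_targets.append(ex.cand_mods[i])
        if val_logps:
            ee_loss = weighted_nll(val_logps, val_targets, [1.0] * len(val_logps))
        if mod_logps:
            mod_loss = weighted_nll(mod_logps, mod_targets, [1.0] * len(mod_logps))
    return {"tr": tr_loss, "rc": rc_loss, "ee": ee_loss, "mod": mod_loss}


def joint_loss(losses: dict[str, Tensor | None]) -> Tensor:
    """Unweighted sum of the per-head NLL terms present in a batch."""
    terms = [t for t in losses.values() if t is not None]
    if not terms:
        raise ValueError("no loss terms")
    return ag.add_n(terms)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def train(
    docs: list[Document],
    schema: EventSchema,
    cfg: TrainConfig,
    vocab: Vocabulary | None = None,
) -> tuple[list[ModelBundle], list[list[dict]]]:
    """Train an ensemble; returns (models, per-member epoch loss histories)."""
    if not docs:
        raise ValueError("empty corpus")
    if vocab is None:
        vocab = Vocabulary.build(docs, schema)
    examples = build_examples(docs, vocab, schema, cap=cfg.candidate_cap)
    bundles: list[ModelBundle] = []
    histories: list[list[dict]] = []
    for member in range(cfg.ensemble_size):
        seed = (cfg.seed + 7919 * member) % (2**31)
        init_rng = np.random.default_rng(seed)
        model = ModelBundle(vocab, cfg.net, init_rng)
        opt = ag.Adam(model.parameters(), lr=cfg.learning_rate,
                      weight_decay=cfg.weight_decay)
        rng = np.random.default_rng(seed + 1)
        history: list[dict] = []
        order = np.arange(len(examples))
        for epoch in range(cfg.epochs):
            rng.shuffle(order)
            sums = {"tr": 0.0, "rc": 0.0, "ee": 0.0, "mod": 0.0}
            counts = {k: 0 for k in sums}
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                batch_losses: list[Tensor] = []
                for idx in batch:
                    losses = sentence_losses(model, examples[idx], cfg, epoch, rng)
                    for k, t in losses.items():
                        if t is not None:
                            sums[k] += t.item()
                            counts[k] += 1
                    batch_losses.append(joint_loss(losses))
                total = ag.add_n(batch_losses).scale(1.0 / len(batch_losses))
                opt.zero_grad()
                total.backward()
                opt.step()
            row = {"epoch": epoch}
            for k in sums:
                row[k] = sums[k] / counts[k] if counts[k] else 0.0
            row["total"] = sum(row[k] for k in sums)
            history.append(row)
            if epoch % 25 == 0 or epoch == cfg.epochs - 1:
                logger.info("member %d epoch %d: %s", member, epoch,
                            {k: round(row[k], 4) for k in ("tr", "rc", "ee", "mod")})
        bundles.append(model)
        histories.append(history)
    return bundles, histories


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def ensemble_combine(per_model_logps: list[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of per-class log-probability vectors across members."""
    return np.mean(np.stack(per_model_logps), axis=0)


def predict_document(
    models: list[ModelBundle],
    doc: Document,
    schema: EventSchema,
    cfg: TrainConfig,
) -> Document:
    """Full prediction pipeline for one document."""
    mode = cfg.mode
    thr_t, thr_r = cfg.threshold_t, cfg.threshold_r
    if mode in ("ee-probability", "zero-threshold"):
        thr_t = thr_r = 0.0
    pred = Document(
        doc_id=doc.doc_id, text=doc.text, sentences=list(doc.sentences),
        tokens=list(doc.tokens), entities=list(doc.entities),
    )
    all_events: list[EventRecord] = []
    for si in range(len(doc.sentences)):
        lo, hi = doc.sentence_token_range(si)
        tokens = doc.tokens[lo:hi]
        if not tokens:
            continue
        ent_labels = entity_labels_for(tokens, doc.entities)
        encs = [m.encoder.encode(tokens, ent_labels) for m in models]
        heads = [m.trigger_head for m in models]
        tp = recognize_triggers(heads, encs, tokens, thr_t, text=doc.text)
        triggers = tp.triggers  # sentence-local token spans
        doc_trigger_of = {
            id(t): replace(t, token_start=t.token_start + lo, token_end=t.token_end + lo)
            for t in triggers
        }
        pred.triggers.extend(doc_trigger_of.values())
        if not triggers:
            continue
        entities = [
            e for e in doc.entities
            if any(t.char_end > e.char_start and t.char_start < e.char_end for t in tokens)
        ]
        pairs = generate_candidate_pairs(triggers, entities, (0, len(tokens)), tokens)
        rels = classify_pairs(
            [m.relation_head for m in models], encs,
            [tp.T[m] for m in range(len(models))], pairs, thr_r, schema=schema,
        )
        emitted = [r for r in rels if r.label != "none"]
        candidates = enumerate_candidate_events(triggers, emitted, schema, cap=cfg.candidate_cap)
        if not candidates:
            continue
        score_candidates(
            [m.event_head for m in models], encs,
            [tp.T[m] for m in range(len(models))], candidates,
        )
        chosen = _select(mode, triggers, emitted, candidates, cfg)
        all_events.extend(_realize(chosen, doc_trigger_of))
    kept = detect_and_discard_loops(all_events)
    kept = _drop_dangling(kept)
    assign_modifications(kept)
    pred.events = kept
    return pred


def _select(
    mode: str,
    triggers: list[TriggerMention],
    relations: list[RelationPrediction],
    candidates: list[CandidateEvent],
    cfg: TrainConfig,
) -> list[CandidateEvent]:
    trig_idx = {id(t): i for i, t in enumerate(triggers)}
    if mode == "rule-all":
        return list(candidates)
    if mode == "rule-single":
        best: dict[int, CandidateEvent] = {}
        for cand in candidates:
            ti = trig_idx[id(cand.trigger)]
            cur = best.get(ti)
            key = (len(cand.relations), sum(r.support for r in cand.relations))
            if cur is None or key > (len(cur.relations), sum(r.support for r in cur.relations)):
                best[ti] = cand
        return [best[ti] for ti in sorted(best)]
    if mode == "ee-probability":
        return [
            c for c in candidates
            if c.s_e > 0
            and c.trigger.support > 0
            and all(r.support > 0 for r in c.relations)
        ]
    # cs / zero-threshold: greedy penalty minimization
    bundle = SupportBundle(
        trigger_support={i: t.support for i, t in enumerate(triggers)},
        relation_support={r.relation_id: r.support for r in relations},
        candidates=[
            BundleCandidate(
                cid=c.candidate_id,
                trigger=trig_idx[id(c.trigger)],
                relations=frozenset(r.relation_id for r in c.relations),
                s_e=c.s_e,
                filler_triggers=frozenset(trig_idx[id(t)] for t in c.filler_triggers),
            )
            for c in candidates
        ],
    )
    result: SelectionResult = select_events_greedy(bundle, cfg.penalty_weights())
    by_cid = {c.candidate_id: c for c in candidates}
    return [by_cid[b.cid] for b in result.chosen]


def _realize(
    chosen: list[CandidateEvent],
    doc_trigger_of: dict[int, TriggerMention],
) -> list[EventRecord]:
    """Instantiate chosen candidates as event records (children first)."""
    # order children before parents so nested fillers resolve
    remaining = list(chosen)
    ordered: list[CandidateEvent] = []
    chosen_triggers = set()
    while remaining:
        progress = False
        for cand in list(remaining):
            if all(id(t) in chosen_triggers for t in cand.filler_triggers):
                ordered.append(cand)
                chosen_triggers.add(id(cand.trigger))
                remaining.remove(cand)
                progress = True
        if not progress:
            for cand in remaining:  # unrealizable (missing children); drop
                logger.debug("dropping unrealizable candidate on trigger %r",
                             cand.trigger.covered_text)
            break
    by_trigger: dict[int, EventRecord] = {}
    out: list[EventRecord] = []
    for cand in ordered:
        trig = doc_trigger_of[id(cand.trigger)]
        args: list[tuple[str, object]] = []
        ok = True
        for rel in cand.relations:
            tgt = rel.pair.target
            if isinstance(tgt, TriggerMention):
                sub = by_trigger.get(id(tgt))
                if sub is None:
                    ok = False
                    break
                args.append((rel.label, sub))
            else:
                args.append((rel.label, tgt))
        if not ok:
            continue
        ev = EventRecord(id=None, trigger=trig, arguments=args, support=cand.s_e)
        if cand.logp_mod is not None:
            ev.logp_mod = tuple(float(x) for x in cand.logp_mod.data)
        prev = by_trigger.get(id(cand.trigger))
        if prev is None or ev.support > prev.support:
            by_trigger[id(cand.trigger)] = ev
        out.append(ev)
    return out


def _drop_dangling(events: list[EventRecord]) -> list[EventRecord]:
    kept = set(id(e) for e in events)
    changed = True
    while changed:
        changed = False
        for ev in events:
            if id(ev) not in kept:
                continue
            for _, f in ev.arguments:
                if isinstance(f, EventRecord) and id(f) not in kept:
                    kept.discard(id(ev))
                    changed = True
                    break
    return [e for e in events if id(e) in kept]


def predict_corpus(
    models: list[ModelBundle],
    docs: list[Document],
    schema: EventSchema,
    cfg: TrainConfig,
) -> list[Document]:
    return [predict_document(models, doc, schema, cfg) for doc in docs]


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_ensemble(models: list[ModelBundle], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vocab = models[0].vocab
    meta = {
        "net": asdict(models[0].net),
        "n_members": len(models),
        "vocab": {
            "words": vocab.words,
            "chars": vocab.chars,
            "entity_labels": vocab.entity_labels,
            "trigger_labels": vocab.trigger_labels,
            "relation_labels": vocab.relation_labels,
            "role_seq_labels": vocab.role_seq_labels,
            "event_types": vocab.event_types,
        },
    }
    (out / "meta.json").write_text(json.dumps(meta), encoding="utf-8")
    for i, model in enumerate(models):
        arrays = {f"p{j}": p.data for j, p in enumerate(model.parameters())}
        np.savez(out / f"member{i}.npz", **arrays)


def load_ensemble(in_dir: str | Path) -> list[ModelBundle]:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text(encoding="utf-8"))
    vocab = Vocabulary(**meta["vocab"])
    net = NetConfig(**meta["net"])
    models: list[ModelBundle] = []
    for i in range(meta["n_members"]):
        model = ModelBundle(vocab, net, np.random.default_rng(0))
        with np.load(src / f"member{i}.npz") as data:
            for j, p in enumerate(model.parameters()):
                p.data[...] = data[f"p{j}"]
        models.append(model)
    return models
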