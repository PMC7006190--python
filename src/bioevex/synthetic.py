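"""Seeded generator of schema-conforming standoff corpora.

Produces documents whose sentences contain typed entity mentions and flat or
nested events with modifications, written in the standoff format and
re-readable by :func:`bioevex.standoff.read_standoff_document`. Trigger and
entity words are drawn from disjoint per-type lexicons (a type-specific stem
plus varying suffixes) with noise words mixed in, so trigger recognition is
learnable from both word identity and character shape but not trivial; each
argument role is cued by its own connector word so relation classification
is learnable from the between-segment. Negation/Speculation modifications
insert a cue word before the trigger. The generator emulates corpus shape
(sentence lengths, entity/event densities, nesting), not realistic
biomedical language.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .schema import EventSchema, SchemaError
from .standoff import Document, EventRecord, read_standoff_document

__all__ = ["SyntheticConfig", "generate_documents", "generate_corpus", "corpus_statistics"]

_START_WORDS = ["The", "These", "Our", "Notably", "Importantly", "Results"]
_NOISE_WORDS = [
    "observed", "cells", "in", "analysis", "levels", "during", "tissue",
    "samples", "assay", "study", "data", "results", "with", "significant",
    "marked", "increased",
]
_CONNECTORS = ["of", "by", "via", "upon", "toward", "under"]
_SUFFIXES = ["ex", "on", "al", "ine", "ase", "ide", "oid", "ium"]
_MOD_CUES = {"Negation": "not", "Speculation": "may"}


@dataclass
class SyntheticConfig:
    """Knobs controlling corpus shape.

    ``event_density`` is the probability that a sentence carries a top-level
    event (a second one is attempted at half that probability);
    ``nesting_prob`` is the chance an event-capable role is filled by a
    sub-event rather than an entity; ``multiword_trigger_prob`` yields
    two-token trigger spans to exercise the B/I/L labels.
    """

    sentences_per_doc: int = 2
    min_sentence_tokens: int = 6
    max_sentence_tokens: int = 12
    entities_per_sentence: int = 2
    event_density: float = 0.85
    nesting_prob: float = 0.35
    modification_prob: float = 0.15
    multiword_trigger_prob: float = 0.15
    optional_role_prob: float = 0.5
    max_nesting_depth: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("event_density", "nesting_prob", "modification_prob",
                     "multiword_trigger_prob", "optional_role_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def type_lexicon(type_name: str) -> list[str]:
    """Disjoint per-type word list: lowercased stem + suffix."""
    stem = type_name.lower()[:6]
    return [stem + s for s in _SUFFIXES]


def role_connector(schema: EventSchema, role: str) -> str:
    roles = schema.role_labels
    return _CONNECTORS[roles.index(role) % len(_CONNECTORS)]


class _DocBuilder:
    def __init__(self) -> None:
        self.words: list[str] = []
        self.char_pos = 0
        self.spans: list[tuple[int, int]] = []

    def add(self, word: str) -> int:
        if self.words:
            self.char_pos += 1  # joining space
        start = self.char_pos
        self.words.append(word)
        self.char_pos += len(word)
        self.spans.append((start, self.char_pos))
        return len(self.words) - 1

    def span(self, i: int, j: int | None = None) -> tuple[int, int]:
        j = i if j is None else j
        return self.spans[i][0], self.spans[j][1]

    def close_sentence(self) -> None:
        # attach terminal punctuation; recorded spans exclude the period
        self.words[-1] += "."
        self.char_pos += 1

    def text(self) -> str:
        return " ".join(self.words)


def _check_satisfiable(schema: EventSchema) -> None:
    for etype, roles in schema.event_types.items():
        for role, spec in roles.items():
            if spec.min_count > 0 and not spec.fillers:
                raise SchemaError(f"{etype}.{role} is mandatory but has no filler categories")


def generate_documents(
    schema: EventSchema,
    cfg: SyntheticConfig,
    n_docs: int,
    doc_prefix: str = "synth",
) -> list[Document]:
    """Generate ``n_docs`` in-memory documents (deterministic in cfg.seed)."""
    _check_satisfiable(schema)
    rng = np.random.default_rng(cfg.seed)
    docs = []
    for d in range(n_docs):
        doc_id = f"{doc_prefix}{d:04d}"
        txt, a1, a2 = _generate_raw(schema, cfg, rng)
        docs.append(read_standoff_document(txt, a1, a2, doc_id=doc_id, schema=schema))
    return docs


def generate_corpus(
    schema: EventSchema,
    cfg: SyntheticConfig,
    n_docs: int,
    out_dir: str | Path,
    doc_prefix: str = "synth",
) -> list[Path]:
    """Generate a corpus on disk (.txt/.a1/.a2 per document)."""
    _check_satisfiable(schema)
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for d in range(n_docs):
        doc_id = f"{doc_prefix}{d:04d}"
        txt, a1, a2 = _generate_raw(schema, cfg, rng)
        read_standoff_document(txt, a1, a2, doc_id=doc_id, schema=schema)  # self-check
        (out / f"{doc_id}.txt").write_text(txt, encoding="utf-8")
        (out / f"{doc_id}.a1").write_text(a1, encoding="utf-8")
        (out / f"{doc_id}.a2").write_text(a2, encoding="utf-8")
        paths.append(out / f"{doc_id}.txt")
    return paths


def _generate_raw(
    schema: EventSchema, cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[str, str, str]:
    builder = _DocBuilder()
    a1_lines: list[str] = []
    a2_t_lines: list[str] = []
    e_specs: list[tuple[str, str, list[tuple[str, str]]]] = []  # (eid, Type:Tid, args)
    m_lines: list[str] = []
    counters = {"T": 0, "E": 0, "M": 0}
    entity_types = sorted(schema.entity_types)
    event_types = schema.event_type_labels

    def new_entity(etype: str) -> str:
        word = str(rng.choice(type_lexicon(etype)))
        i = builder.add(word)
        s, e = builder.span(i)
        counters["T"] += 1
        tid = f"T{counters['T']}"
        a1_lines.append(f"{tid}\t{etype} {s} {e}\t{word}")
        return tid

    def trigger_line(etype: str, i: int, j: int) -> str:
        s, e = builder.span(i, j)
        counters["T"] += 1
        tid = f"T{counters['T']}"
        a2_t_lines.append(f"{tid}\t{etype} {s} {e}\t{builder.text()[s:e]}")
        return tid

    def emit_event(etype: str, depth: int) -> str | None:
        """Append an event clause to the sentence; returns its E id."""
        if depth > 6:
            raise SchemaError(
                "mandatory event-valued roles force unbounded nesting; schema unsatisfiable"
            )
        specs = schema.roles_for(etype)
        # choose fillers first so unsatisfiable choices can back off to entities
        mod = None
        if depth == 0 and rng.random() < cfg.modification_prob:
            mod = "Negation" if rng.random() < 0.5 else "Speculation"
            builder.add(_MOD_CUES[mod])
        lex = type_lexicon(etype)
        if rng.random() < cfg.multiword_trigger_prob:
            i = builder.add(str(rng.choice(["early", "late", "strong"])))
            j = builder.add(str(rng.choice(lex)))
        else:
            i = j = builder.add(str(rng.choice(lex)))
        trig_id = trigger_line(etype, i, j)
        args: list[tuple[str, str]] = []
        for role in sorted(specs):
            spec = specs[role]
            count = spec.min_count
            if spec.max_count > spec.min_count and rng.random() < cfg.optional_role_prob:
                count += 1
            for _ in range(count):
                builder.add(role_connector(schema, role))
                event_fillers = [f for f in sorted(spec.fillers) if f in schema.event_types]
                entity_fillers = [f for f in sorted(spec.fillers) if f in schema.entity_types]
                use_event = (
                    event_fillers
                    and depth < cfg.max_nesting_depth
                    and (not entity_fillers or rng.random() < cfg.nesting_prob)
                )
                if use_event:
                    sub_eid = emit_event(str(rng.choice(event_fillers)), depth + 1)
                    args.append((role, sub_eid))
                elif entity_fillers:
                    args.append((role, new_entity(str(rng.choice(entity_fillers)))))
                else:  # mandatory event-only role beyond depth: nest anyway
                    sub_eid = emit_event(str(rng.choice(event_fillers)), depth + 1)
                    args.append((role, sub_eid))
        counters["E"] += 1
        eid = f"E{counters['E']}"
        e_specs.append((eid, f"{etype}:{trig_id}", args))
        if mod is not None:
            counters["M"] += 1
            m_lines.append(f"M{counters['M']}\t{mod} {eid}")
        return eid

    for _ in range(cfg.sentences_per_doc):
        sent_start_idx = len(builder.words)
        builder.add(str(rng.choice(_START_WORDS)))
        n_events = int(rng.random() < cfg.event_density)
        if n_events and rng.random() < cfg.event_density / 2:
            n_events += 1
        for _ in range(n_events):
            emit_event(str(rng.choice(event_types)), depth=0)
        for _ in range(int(rng.integers(0, cfg.entities_per_sentence + 1))):
            builder.add("in")
            new_entity(str(rng.choice(entity_types)))
        target_len = int(rng.integers(cfg.min_sentence_tokens, cfg.max_sentence_tokens + 1))
        while len(builder.words) - sent_start_idx < target_len:
            builder.add(str(rng.choice(_NOISE_WORDS)))
        builder.close_sentence()

    text = builder.text()
    a2_lines = list(a2_t_lines)
    for eid, head, args in e_specs:
        parts = [head] + [f"{r}:{ref}" for r, ref in args]
        a2_lines.append(f"{eid}\t{' '.join(parts)}")
    a2_lines.extend(m_lines)
    return text, "\n".join(a1_lines) + ("\n" if a1_lines else ""), \
        "\n".join(a2_lines) + ("\n" if a2_lines else "")


def corpus_statistics(docs: list[Document]) -> dict:
    """Count table over a corpus (documents, words, entities, events, types)."""
    stats: dict = {
        "documents": len(docs),
        "sentences": 0,
        "words": 0,
        "entities": 0,
        "events": 0,
        "modifications": 0,
        "nested_events": 0,
        "entity_types": {},
        "event_types": {},
    }
    for doc in docs:
        stats["sentences"] += len(doc.sentences)
        stats["words"] += len(doc.tokens)
        stats["entities"] += len(doc.entities)
        stats["events"] += len(doc.events)
        for ent in doc.entities:
            stats["entity_types"][ent.entity_type] = (
                stats["entity_types"].get(ent.entity_type, 0) + 1
            )
        for ev in doc.events:
            stats["event_types"][ev.trigger.event_type] = (
                stats["event_types"].get(ev.trigger.event_type, 0) + 1
            )
            if ev.modification:
                stats["modifications"] += 1
            if any(isinstance(f, EventRecord) for _, f in ev.arguments):
                stats["nested_events"] += 1
    return stats
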