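"""BioNLP-ST standoff data model and I/O.

Documents are plain text plus annotation files: ``.a1`` holds given entity
mentions, ``.a2`` holds event triggers (T lines), events (E lines) and
modifications (M lines). Character offsets are 0-based half-open, following
the brat convention. Sentence splitting and tokenization are self-contained
rule-based procedures (no external NLP toolkit); the BILOU codec maps trigger
spans to/from per-token label sequences.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

from .schema import EventSchema

logger = logging.getLogger(__name__)

__all__ = [
    "Token",
    "EntityMention",
    "TriggerMention",
    "EventRecord",
    "Document",
    "StandoffError",
    "StandoffParseError",
    "StandoffIntegrityError",
    "StandoffReferenceError",
    "StandoffSerializationError",
    "BilouOverlapError",
    "split_sentences",
    "tokenize",
    "encode_bilou",
    "decode_bilou",
    "read_standoff_document",
    "write_standoff",
    "MODIFICATION_LABELS",
]

MODIFICATION_LABELS = ("Negation", "Speculation")


class StandoffError(Exception):
    """Base class for standoff I/O failures."""


class StandoffParseError(StandoffError):
    pass


class StandoffIntegrityError(StandoffError):
    pass


class StandoffReferenceError(StandoffError):
    pass


class StandoffSerializationError(StandoffError):
    pass


class BilouOverlapError(ValueError):
    """Raised when trigger spans overlap and cannot share BILOU labels."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Token:
    text: str
    char_start: int
    char_end: int
    sentence_index: int = 0


@dataclass(frozen=True)
class EntityMention:
    id: str
    entity_type: str
    char_start: int
    char_end: int
    covered_text: str


@dataclass(frozen=True)
class TriggerMention:
    id: str | None
    event_type: str
    char_start: int
    char_end: int
    covered_text: str
    token_start: int = -1  # document-level token indices, inclusive start
    token_end: int = -1  # exclusive end
    sentence_index: int = -1
    support: float = 0.0


@dataclass
class EventRecord:
    id: str | None
    trigger: TriggerMention
    # filler is an EntityMention or another EventRecord
    arguments: list[tuple[str, object]] = field(default_factory=list)
    modification: str | None = None
    support: float = 0.0
    logp_mod: tuple[float, float, float] | None = None


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[tuple[int, int]] = field(default_factory=list)
    tokens: list[Token] = field(default_factory=list)
    entities: list[EntityMention] = field(default_factory=list)
    triggers: list[TriggerMention] = field(default_factory=list)
    events: list[EventRecord] = field(default_factory=list)

    def sentence_token_range(self, sentence_index: int) -> tuple[int, int]:
        """Document-token index range [start, end) of a sentence."""
        start = None
        end = 0
        for i, tok in enumerate(self.tokens):
            if tok.sentence_index == sentence_index:
                if start is None:
                    start = i
                end = i + 1
        return (start if start is not None else 0, end)


# ---------------------------------------------------------------------------
# Sentence splitting & tokenization
# ---------------------------------------------------------------------------

# abbreviations that do not end a sentence even when followed by a capital
_ABBREVIATIONS = {
    "e.g.", "i.e.", "etc.", "vs.", "cf.", "fig.", "figs.", "dr.", "al.",
    "st.", "no.", "ref.", "approx.",
}

_BOUNDARY_RE = re.compile(r"[.?!]+(?=\s+[A-Z0-9(])")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Split text into sentence character spans.

    A sentence boundary is terminal punctuation ([.?!]) followed by
    whitespace and a capital letter, digit or opening bracket, unless the
    word ending at the punctuation is a known abbreviation. Spans cover the
    annotated region tightly (leading/trailing whitespace excluded) and
    together partition the non-whitespace text.
    """
    if not text.strip():
        return []
    boundaries: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()
        # word ending at the punctuation, lowercased
        ws = text.rfind(" ", 0, m.start())
        word = text[ws + 1 : end].lower()
        if word in _ABBREVIATIONS:
            continue
        boundaries.append(end)
    spans: list[tuple[int, int]] = []
    start = 0
    for b in boundaries + [len(text)]:
        chunk = text[start:b]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        if chunk.strip():
            spans.append((start + lead, b - trail))
        start = b
    return spans


# punctuation detached from word edges; internal hyphens/slashes are kept
_PUNCT = set("()[]{}.,;:!?\"'`%")


def tokenize(sentence_text: str, offset: int = 0, sentence_index: int = 0) -> list[Token]:
    """Whitespace tokenization with edge-punctuation detachment.

    Leading/trailing punctuation characters become their own tokens;
    word-internal hyphens and slashes (biomedical names) are preserved.
    Offsets are exact slices of the enclosing document text when ``offset``
    is the sentence start.
    """
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", sentence_text):
        chunk, start = m.group(), m.start()
        # peel leading punctuation
        left = 0
        while left < len(chunk) and chunk[left] in _PUNCT:
            left += 1
        right = len(chunk)
        while right > left and chunk[right - 1] in _PUNCT:
            right -= 1
        pieces: list[tuple[int, int]] = []
        pieces.extend((i, i + 1) for i in range(0, left))
        if right > left:
            pieces.append((left, right))
        pieces.extend((i, i + 1) for i in range(right, len(chunk)))
        for s, e in pieces:
            tokens.append(
                Token(
                    text=chunk[s:e],
                    char_start=offset + start + s,
                    char_end=offset + start + e,
                    sentence_index=sentence_index,
                )
            )
    return tokens


def tokenize_document(text: str) -> tuple[list[tuple[int, int]], list[Token]]:
    sentences = split_sentences(text)
    tokens: list[Token] = []
    for si, (s, e) in enumerate(sentences):
        tokens.extend(tokenize(text[s:e], offset=s, sentence_index=si))
    return sentences, tokens


# ---------------------------------------------------------------------------
# BILOU codec
# ---------------------------------------------------------------------------


def encode_bilou(tokens: list[Token], triggers: list[TriggerMention]) -> list[str]:
    """Encode trigger token spans as BILOU labels over the tokens.

    Raises :class:`BilouOverlapError` when trigger spans overlap; the caller
    resolves the conflict (the reader keeps the first by file order).
    """
    labels = ["O"] * len(tokens)
    owner: list[TriggerMention | None] = [None] * len(tokens)
    for trig in triggers:
        if trig.token_start < 0 or trig.token_end <= trig.token_start:
            raise ValueError(f"trigger {trig.id} has no token span")
        for i in range(trig.token_start, trig.token_end):
            if owner[i] is not None:
                raise BilouOverlapError(
                    f"triggers {owner[i].id} and {trig.id} overlap at token {i}"
                )
            owner[i] = trig
        span = range(trig.token_start, trig.token_end)
        if len(span) == 1:
            labels[span[0]] = f"U-{trig.event_type}"
        else:
            labels[span[0]] = f"B-{trig.event_type}"
            for i in span[1:-1]:
                labels[i] = f"I-{trig.event_type}"
            labels[span[-1]] = f"L-{trig.event_type}"
    return labels


def decode_bilou(labels: list[str], tokens: list[Token]) -> list[TriggerMention]:
    """Decode a (possibly ill-formed) BILOU sequence into trigger spans.

    Total on arbitrary label noise. Repair rules: orphan I opens a span like
    B; orphan L acts as U; a span's type is fixed by its opening token; a
    span left open at O/B/U or sequence end is closed at the previous token.
    """
    spans: list[tuple[int, int, str]] = []
    open_start: int | None = None
    open_type: str | None = None

    def close(upto: int) -> None:
        nonlocal open_start, open_type
        if open_start is not None:
            spans.append((open_start, upto, open_type))
            open_start, open_type = None, None

    for i, label in enumerate(labels):
        if label == "O" or "-" not in label:
            close(i)
            continue
        prefix, etype = label.split("-", 1)
        if prefix == "U":
            close(i)
            spans.append((i, i + 1, etype))
        elif prefix == "B":
            close(i)
            open_start, open_type = i, etype
        elif prefix == "I":
            if open_start is None:
                open_start, open_type = i, etype  # orphan I -> B
        elif prefix == "L":
            if open_start is None:
                spans.append((i, i + 1, etype))  # orphan L -> U
            else:
                spans.append((open_start, i + 1, open_type))
                open_start, open_type = None, None
        else:
            close(i)
    close(len(labels))

    out: list[TriggerMention] = []
    for ts, te, etype in spans:
        cs, ce = tokens[ts].char_start, tokens[te - 1].char_end
        out.append(
            TriggerMention(
                id=None,
                event_type=etype,
                char_start=cs,
                char_end=ce,
                covered_text="",
                token_start=ts,
                token_end=te,
                sentence_index=tokens[ts].sentence_index,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Standoff reading
# ---------------------------------------------------------------------------

_T_LINE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_E_LINE = re.compile(r"^(E\d+)\t(.+)$")
_M_LINE = re.compile(r"^(M\d+)\t(\S+) (E\d+)$")


def _token_span_for(char_start: int, char_end: int, tokens: list[Token]) -> tuple[int, int] | None:
    idx = [i for i, t in enumerate(tokens) if t.char_end > char_start and t.char_start < char_end]
    if not idx:
        return None
    if idx != list(range(idx[0], idx[-1] + 1)):
        return None
    return idx[0], idx[-1] + 1


def read_standoff_document(
    txt_text: str,
    a1_text: str,
    a2_text: str | None = None,
    doc_id: str = "doc",
    schema: EventSchema | None = None,
) -> Document:
    """Parse a standoff document (text + .a1 entities + optional .a2 events).

    All character offsets are verified against the text; dangling E/M
    references raise :class:`StandoffReferenceError`. Cross-sentence triggers
    or arguments are dropped with a warning (single-sentence scope), as are
    gold triggers overlapping an earlier trigger (one label per word).
    """
    sentences, tokens = tokenize_document(txt_text)
    doc = Document(doc_id=doc_id, text=txt_text, sentences=sentences, tokens=tokens)

    def parse_t_line(line: str, lineno: int, source: str) -> tuple[str, str, int, int, str]:
        m = _T_LINE.match(line)
        if not m:
            raise StandoffParseError(f"{source} line {lineno}: malformed T line: {line!r}")
        tid, ttype, s, e, covered = m.group(1), m.group(2), int(m.group(3)), int(m.group(4)), m.group(5)
        if not (0 <= s < e <= len(txt_text)):
            raise StandoffIntegrityError(
                f"{source} line {lineno}: span {s}:{e} outside document bounds"
            )
        if txt_text[s:e] != covered:
            raise StandoffIntegrityError(
                f"{source} line {lineno}: quoted text {covered!r} != text slice {txt_text[s:e]!r}"
            )
        return tid, ttype, s, e, covered

    for lineno, line in enumerate(_annotation_lines(a1_text), start=1):
        tid, ttype, s, e, covered = parse_t_line(line, lineno, "a1")
        doc.entities.append(EntityMention(tid, ttype, s, e, covered))

    if not a2_text or not a2_text.strip():
        return doc

    triggers: dict[str, TriggerMention] = {}
    event_lines: list[tuple[int, str, str]] = []
    mod_lines: list[tuple[int, str, str]] = []
    occupied: list[TriggerMention | None] = [None] * len(tokens)

    for lineno, line in enumerate(_annotation_lines(a2_text), start=1):
        if line.startswith("T"):
            tid, ttype, s, e, covered = parse_t_line(line, lineno, "a2")
            span = _token_span_for(s, e, tokens)
            if span is None:
                logger.warning("%s: trigger %s has no contiguous token span; dropped", doc_id, tid)
                continue
            ts, te = span
            if tokens[ts].sentence_index != tokens[te - 1].sentence_index:
                logger.warning("%s: trigger %s crosses a sentence boundary; dropped", doc_id, tid)
                continue
            conflict = next((occupied[i] for i in range(ts, te) if occupied[i] is not None), None)
            if conflict is not None:
                logger.warning(
                    "%s: trigger %s overlaps %s; keeping the first by file order",
                    doc_id, tid, conflict.id,
                )
                continue
            trig = TriggerMention(
                id=tid, event_type=ttype, char_start=s, char_end=e, covered_text=covered,
                token_start=ts, token_end=te, sentence_index=tokens[ts].sentence_index,
            )
            for i in range(ts, te):
                occupied[i] = trig
            triggers[tid] = trig
        elif line.startswith("E"):
            m = _E_LINE.match(line)
            if not m:
                raise StandoffParseError(f"a2 line {lineno}: malformed E line: {line!r}")
            event_lines.append((lineno, m.group(1), m.group(2)))
        elif line.startswith("M"):
            m = _M_LINE.match(line)
            if not m:
                raise StandoffParseError(f"a2 line {lineno}: malformed M line: {line!r}")
            if m.group(2) not in MODIFICATION_LABELS:
                raise StandoffParseError(
                    f"a2 line {lineno}: unknown modification {m.group(2)!r}"
                )
            mod_lines.append((lineno, m.group(2), m.group(3)))
        else:
            raise StandoffParseError(f"a2 line {lineno}: unrecognized line: {line!r}")

    doc.triggers = list(triggers.values())
    entities_by_id = {e.id: e for e in doc.entities}

    # two passes: create events, then resolve fillers (forward E refs allowed)
    events: dict[str, EventRecord] = {}
    raw_args: dict[str, list[tuple[str, str]]] = {}
    for lineno, eid, body in event_lines:
        parts = body.split()
        head = parts[0].split(":", 1)
        if len(head) != 2:
            raise StandoffParseError(f"a2 line {lineno}: malformed event head {parts[0]!r}")
        etype, trig_id = head
        if trig_id not in triggers:
            if trig_id in entities_by_id or _looks_like_tid(trig_id):
                raise StandoffReferenceError(
                    f"a2 line {lineno}: event {eid} references unknown trigger {trig_id}"
                )
            raise StandoffParseError(f"a2 line {lineno}: bad trigger reference {trig_id!r}")
        if triggers[trig_id].event_type != etype:
            raise StandoffIntegrityError(
                f"a2 line {lineno}: event type {etype} != trigger type {triggers[trig_id].event_type}"
            )
        args: list[tuple[str, str]] = []
        for part in parts[1:]:
            if ":" not in part:
                raise StandoffParseError(f"a2 line {lineno}: malformed argument {part!r}")
            role, ref = part.split(":", 1)
            args.append((role, ref))
        events[eid] = EventRecord(id=eid, trigger=triggers[trig_id])
        raw_args[eid] = args

    for eid, args in raw_args.items():
        for role, ref in args:
            if ref.startswith("E"):
                if ref not in events:
                    raise StandoffReferenceError(
                        f"event {eid}: dangling event reference {ref}"
                    )
                events[eid].arguments.append((role, events[ref]))
            else:
                if ref not in entities_by_id:
                    raise StandoffReferenceError(
                        f"event {eid}: dangling entity reference {ref}"
                    )
                events[eid].arguments.append((role, entities_by_id[ref]))

    for lineno, mod, eid in mod_lines:
        if eid not in events:
            raise StandoffReferenceError(f"a2 line {lineno}: dangling event reference {eid}")
        events[eid].modification = mod

    if _has_cycle(list(events.values())):
        raise StandoffIntegrityError("event graph contains a cycle")

    if schema is not None:
        for ev in events.values():
            cats = [
                (role, f.entity_type if isinstance(f, EntityMention) else f.trigger.event_type)
                for role, f in ev.arguments
            ]
            violations = schema.validate_args(ev.trigger.event_type, cats)
            if violations:
                raise StandoffIntegrityError(f"event {ev.id}: {'; '.join(violations)}")

    doc.events = list(events.values())
    return doc


def _annotation_lines(text: str) -> list[str]:
    return [ln for ln in text.splitlines() if ln.strip()]


def _looks_like_tid(ref: str) -> bool:
    return bool(re.fullmatch(r"T\d+", ref))


def _has_cycle(events: list[EventRecord]) -> bool:
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[int, int] = {}

    def visit(ev: EventRecord) -> bool:
        color[id(ev)] = GRAY
        for _, filler in ev.arguments:
            if isinstance(filler, EventRecord):
                c = color.get(id(filler), WHITE)
                if c == GRAY:
                    return True
                if c == WHITE and visit(filler):
                    return True
        color[id(ev)] = BLACK
        return False

    return any(color.get(id(ev), WHITE) == WHITE and visit(ev) for ev in events)


# ---------------------------------------------------------------------------
# Standoff writing
# ---------------------------------------------------------------------------


def write_standoff(doc: Document) -> str:
    """Serialize a document's triggers/events/modifications to a2 text.

    Trigger identifiers continue after the a1 entity numbering; event
    identifiers are renumbered E1.. in a topological (children-first) order
    so every reference points at an already-written line. Raises
    :class:`StandoffSerializationError` on a cyclic event graph.
    """
    if _has_cycle(doc.events):
        raise StandoffSerializationError("cyclic event graph cannot be serialized")

    max_t = 0
    for ent in doc.entities:
        m = re.fullmatch(r"T(\d+)", ent.id)
        if m:
            max_t = max(max_t, int(m.group(1)))

    lines: list[str] = []
    trig_ids: dict[int, str] = {}
    used_triggers: list[TriggerMention] = []
    seen_trig: dict[tuple[int, int, str], TriggerMention] = {}
    for trig in list(doc.triggers) + [ev.trigger for ev in doc.events]:
        key = (trig.char_start, trig.char_end, trig.event_type)
        if key in seen_trig:
            trig_ids[id(trig)] = ""  # resolved after numbering below
            continue
        seen_trig[key] = trig
        used_triggers.append(trig)
    for i, trig in enumerate(used_triggers, start=max_t + 1):
        tid = f"T{i}"
        trig_ids[id(trig)] = tid
        covered = doc.text[trig.char_start:trig.char_end]
        lines.append(f"{tid}\t{trig.event_type} {trig.char_start} {trig.char_end}\t{covered}")
    for trig in list(doc.triggers) + [ev.trigger for ev in doc.events]:
        if trig_ids.get(id(trig)) == "":
            key = (trig.char_start, trig.char_end, trig.event_type)
            trig_ids[id(trig)] = trig_ids[id(seen_trig[key])]

    event_ids: dict[int, str] = {}
    order: list[EventRecord] = []

    def emit(ev: EventRecord) -> None:
        if id(ev) in event_ids:
            return
        event_ids[id(ev)] = ""  # mark in progress; cycles already excluded
        for _, filler in ev.arguments:
            if isinstance(filler, EventRecord):
                emit(filler)
        order.append(ev)

    for ev in doc.events:
        emit(ev)
    for i, ev in enumerate(order, start=1):
        event_ids[id(ev)] = f"E{i}"

    for ev in order:
        parts = [f"{ev.trigger.event_type}:{trig_ids[id(ev.trigger)]}"]
        for role, filler in ev.arguments:
            if isinstance(filler, EventRecord):
                parts.append(f"{role}:{event_ids[id(filler)]}")
            else:
                parts.append(f"{role}:{filler.id}")
        lines.append(f"{event_ids[id(ev)]}\t{' '.join(parts)}")

    mod_no = 1
    for ev in order:
        if ev.modification:
            lines.append(f"M{mod_no}\t{ev.modification} {event_ids[id(ev)]}")
            mod_no += 1

    return "\n".join(lines) + ("\n" if lines else "")


def read_corpus_dir(
    corpus_dir, schema: EventSchema | None = None, with_a2: bool = True
) -> list[Document]:
    """Read every ``*.txt`` (+ ``.a1``/``.a2`` siblings) under a directory."""
    from pathlib import Path

    root = Path(corpus_dir)
    docs: list[Document] = []
    for txt_path in sorted(root.glob("*.txt")):
        a1 = txt_path.with_suffix(".a1")
        a2 = txt_path.with_suffix(".a2")
        docs.append(
            read_standoff_document(
                txt_path.read_text(encoding="utf-8"),
                a1.read_text(encoding="utf-8") if a1.exists() else "",
                a2.read_text(encoding="utf-8") if (with_a2 and a2.exists()) else None,
                doc_id=txt_path.stem,
                schema=schema,
            )
        )
    return docs


def write_a1(doc: Document) -> str:
    lines = [
        f"{e.id}\t{e.entity_type} {e.char_start} {e.char_end}\t{e.covered_text}"
        for e in doc.entities
    ]
    return "\n".join(lines) + ("\n" if lines else "")
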