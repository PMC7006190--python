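"""Standoff parsing/serialization, sentence splitting, tokenizer, BILOU codec."""

import pytest
from hypothesis import given, strategies as st

import bioevex as bx
from bioevex.standoff import (
    BilouOverlapError,
    StandoffIntegrityError,
    StandoffParseError,
    StandoffReferenceError,
    StandoffSerializationError,
    Token,
    TriggerMention,
    tokenize_document,
    write_a1,
)

from conftest import FIG_A1, FIG_A2, FIG_TEXT


class TestReadStandoff:
    def test_nested_event_parsed(self, nested_doc):
        assert len(nested_doc.entities) == 2
        assert len(nested_doc.triggers) == 2
        assert len(nested_doc.events) == 2
        reg = next(e for e in nested_doc.events if e.trigger.event_type == "Regulation")
        exp = next(e for e in nested_doc.events if e.trigger.event_type == "Expression")
        cause = dict(reg.arguments)["Cause"]
        assert cause is exp, "expression event nests as the regulation's Cause"
        assert reg.modification == "Negation"
        assert exp.trigger.covered_text == "over-expression"

    def test_empty_a2_gives_entities_only(self):
        doc = bx.read_standoff_document(FIG_TEXT, FIG_A1, "")
        assert len(doc.entities) == 2 and doc.events == [] and doc.triggers == []

    def test_offset_mismatch_is_integrity_error(self):
        bad_a1 = "T1\tGene 35 40\twrong\n"
        with pytest.raises(StandoffIntegrityError):
            bx.read_standoff_document(FIG_TEXT, bad_a1)

    def test_malformed_line_names_line_number(self):
        with pytest.raises(StandoffParseError, match="line 1"):
            bx.read_standoff_document(FIG_TEXT, "T1\tGene 35\tlamin\n")

    def test_dangling_reference_raises(self):
        a2 = "T3\tExpression 16 31\tover-expression\nE1\tExpression:T3 Theme:T9\n"
        with pytest.raises(StandoffReferenceError):
            bx.read_standoff_document(FIG_TEXT, FIG_A1, a2)

    def test_overlapping_gold_triggers_keep_first(self, caplog):
        a2 = (
            "T3\tExpression 16 31\tover-expression\n"
            "T4\tRegulation 16 31\tover-expression\n"
        )
        doc = bx.read_standoff_document(FIG_TEXT, FIG_A1, a2)
        assert [t.id for t in doc.triggers] == ["T3"]


class TestWriteStandoff:
    def test_round_trip_preserves_structure(self, nested_doc, toy_schema):
        a2 = bx.write_standoff(nested_doc)
        re_read = bx.read_standoff_document(FIG_TEXT, write_a1(nested_doc), a2,
                                            schema=toy_schema)
        assert bx.score_corpus([nested_doc], [re_read]).f1 == 1.0
        assert sorted(e.modification or "" for e in re_read.events) == ["", "Negation"]

    def test_negation_written_as_m_line(self, nested_doc):
        a2 = bx.write_standoff(nested_doc)
        m_lines = [l for l in a2.splitlines() if l.startswith("M")]
        assert len(m_lines) == 1 and m_lines[0].split("\t")[1].startswith("Negation E")

    def test_no_events_writes_trigger_only_or_empty(self):
        doc = bx.read_standoff_document(FIG_TEXT, FIG_A1, "")
        assert bx.write_standoff(doc) == ""

    def test_cyclic_graph_refuses(self, nested_doc):
        reg = next(e for e in nested_doc.events if e.trigger.event_type == "Regulation")
        exp = next(e for e in nested_doc.events if e.trigger.event_type == "Expression")
        exp.arguments.append(("Theme", reg))  # manufacture a cycle
        with pytest.raises(StandoffSerializationError):
            bx.write_standoff(nested_doc)


class TestSentenceSplitting:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("A b. C d.", ["A b.", "C d."]),
            ("no terminal punctuation here", ["no terminal punctuation here"]),
            ("Genes e.g. lamin are expressed. Next sentence.",
             ["Genes e.g. lamin are expressed.", "Next sentence."]),
            ("Was it expressed? Yes it was.", ["Was it expressed?", "Yes it was."]),
        ],
    )
    def test_split_examples(self, text, expected):
        spans = bx.split_sentences(text)
        assert [text[s:e] for s, e in spans] == expected

    def test_empty_text(self):
        assert bx.split_sentences("   ") == []


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("over-expression promote tumorigenesis.",
             ["over-expression", "promote", "tumorigenesis", "."]),
            ("", []),
            ("(p53)", ["(", "p53", ")"]),
            ("TGF-beta/Smad pathway", ["TGF-beta/Smad", "pathway"]),
        ],
    )
    def test_examples(self, text, expected):
        assert [t.text for t in bx.tokenize(text)] == expected

    def test_offsets_reconstruct_text(self):
        text = "The (p53) gene, i.e. TP53, is mutated."
        for tok in bx.tokenize(text):
            assert text[tok.char_start:tok.char_end] == tok.text

    @given(st.lists(st.text(alphabet="abcXY().,-", min_size=1, max_size=8), max_size=8))
    def test_offsets_exact_for_random_words(self, words):
        text = " ".join(words)
        for tok in bx.tokenize(text):
            assert text[tok.char_start:tok.char_end] == tok.text


def _tokens(n):
    return [Token(text=f"w{i}", char_start=3 * i, char_end=3 * i + 2, sentence_index=0)
            for i in range(n)]


def _trigger(ts, te, etype="Expression"):
    toks = _tokens(te)
    return TriggerMention(id=None, event_type=etype, char_start=toks[ts].char_start,
                          char_end=toks[te - 1].char_end, covered_text="",
                          token_start=ts, token_end=te, sentence_index=0)


class TestBilouCodec:
    def test_multi_token_span(self):
        labels = bx.encode_bilou(_tokens(5), [_trigger(1, 4, "X")])
        assert labels == ["O", "B-X", "I-X", "L-X", "O"]

    def test_no_triggers_all_outside(self):
        assert bx.encode_bilou(_tokens(3), []) == ["O", "O", "O"]

    def test_overlap_raises_naming_conflict(self):
        with pytest.raises(BilouOverlapError):
            bx.encode_bilou(_tokens(4), [_trigger(0, 2), _trigger(1, 3)])

    def test_decode_example(self):
        spans = bx.decode_bilou(["O", "B-X", "L-X", "O", "U-Y"], _tokens(5))
        assert [(t.token_start, t.token_end, t.event_type) for t in spans] == [
            (1, 3, "X"), (4, 5, "Y")]

    def test_orphan_inside_repaired_to_unit(self):
        spans = bx.decode_bilou(["I-X"], _tokens(1))
        assert [(t.token_start, t.token_end, t.event_type) for t in spans] == [(0, 1, "X")]

    def test_type_conflict_resolved_by_opener(self):
        spans = bx.decode_bilou(["B-X", "I-Y", "L-Y"], _tokens(3))
        assert [(t.token_start, t.token_end, t.event_type) for t in spans] == [(0, 3, "X")]

    @given(
        st.integers(min_value=1, max_value=12).flatmap(
            lambda n: st.tuples(
                st.just(n),
                st.lists(
                    st.tuples(st.integers(0, n - 1), st.integers(1, 3),
                              st.sampled_from(["X", "Y"])),
                    max_size=4,
                ),
            )
        )
    )
    def test_encode_decode_round_trip(self, case):
        n, raw = case
        spans, used = [], set()
        for start, length, etype in raw:
            end = min(start + length, n)
            if end <= start or any(i in used for i in range(start, end)):
                continue
            used.update(range(start, end))
            spans.append(_trigger(start, end, etype))
        toks = _tokens(n)
        decoded = bx.decode_bilou(bx.encode_bilou(toks, spans), toks)
        assert sorted((t.token_start, t.token_end, t.event_type) for t in decoded) == \
            sorted((t.token_start, t.token_end, t.event_type) for t in spans)

    @given(st.lists(st.sampled_from(
        ["O", "B-X", "I-X", "L-X", "U-X", "B-Y", "I-Y", "L-Y", "U-Y", "garbage"]),
        min_size=0, max_size=15))
    def test_decode_total_on_arbitrary_noise(self, labels):
        spans = bx.decode_bilou(labels, _tokens(len(labels)))
        for t in spans:
            assert 0 <= t.token_start < t.token_end <= len(labels)


def test_tokenize_document_partitions_sentences():
    text = "The gene is expressed. The cancer was not observed."
    sentences, tokens = tokenize_document(text)
    assert len(sentences) == 2
    for tok in tokens:
        s, e = sentences[tok.sentence_index]
        assert s <= tok.char_start and tok.char_end <= e
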