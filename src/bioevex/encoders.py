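"""Shared sentence encoder: character-level CNN + entity-aware BiLSTM.

Each word is represented as v_i = [w_i, e_i, ch_i]: a word embedding, an
entity-label embedding and a character-level convolutional feature (max over
window responses, so the char vector has fixed length regardless of word
length). A bidirectional LSTM over the v_i yields the hidden sequence
H = {h_1..h_n} with h_i = [forward h_i, backward h_i]; H together with the
entity embedding sequence E is shared by all downstream heads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .schema import EventSchema
from .standoff import EntityMention, Token

__all__ = [
    "NetConfig",
    "Vocabulary",
    "CharCNN",
    "LSTMDirection",
    "BiLSTMLayer",
    "SentenceEncoding",
    "Encoder",
    "entity_labels_for",
]

PAD_CHAR = "\x00"
UNK = "<unk>"

BILOU_PREFIXES = ("B", "I", "L", "U")


@dataclass
class NetConfig:
    """Network dimensions and regularisation settings.

    All sizes are the package's declared defaults, chosen small enough for
    CPU training on synthetic corpora while leaving each component with
    clearly non-trivial capacity.
    """

    char_dim: int = 16
    kernel_size: int = 3
    channels: int = 16
    word_dim: int = 32
    entity_dim: int = 8
    hidden: int = 32
    dropout: float = 0.5
    encoder_layers: int = 1
    trigger_label_dim: int = 8
    head_hidden: int = 64
    distance_dim: int = 8
    distance_clip: int = 30
    mid_kernel: int = 3
    mid_channels: int = 16
    role_dim: int = 8
    use_char_cnn: bool = True

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.channels < 1:
            raise ValueError("kernel_size and channels must be >= 1")


@dataclass
class Vocabulary:
    """Closed label inventories plus word/char lookup tables.

    Class index 0 is reserved for the *none* class in every inventory
    (the ``O`` BILOU label, the ``none`` relation, the ``none_type`` role),
    so support values are always margins over index 0.
    """

    words: dict[str, int]
    chars: dict[str, int]
    entity_labels: list[str]
    trigger_labels: list[str]  # "O" first, then BILOU x event types
    relation_labels: list[str]  # "none" first, then roles
    role_seq_labels: list[str]  # "none_type", "event_trigger", then roles
    event_types: list[str]

    @classmethod
    def build(cls, documents, schema: EventSchema) -> "Vocabulary":
        words = {UNK: 0}
        chars = {PAD_CHAR: 0, UNK: 1}
        for doc in documents:
            for tok in doc.tokens:
                words.setdefault(tok.text.lower(), len(words))
                for ch in tok.text:
                    chars.setdefault(ch, len(chars))
        event_types = schema.event_type_labels
        trigger_labels = ["O"] + [
            f"{p}-{t}" for t in event_types for p in BILOU_PREFIXES
        ]
        relation_labels = ["none"] + schema.role_labels
        role_seq_labels = ["none_type", "event_trigger"] + schema.role_labels
        entity_labels = ["O"] + sorted(schema.entity_types)
        return cls(
            words=words,
            chars=chars,
            entity_labels=entity_labels,
            trigger_labels=trigger_labels,
            relation_labels=relation_labels,
            role_seq_labels=role_seq_labels,
            event_types=event_types,
        )

    def word_id(self, text: str) -> int:
        return self.words.get(text.lower(), 0)

    def char_ids(self, text: str, min_len: int) -> np.ndarray:
        ids = [self.chars.get(ch, 1) for ch in text]
        while len(ids) < min_len:
            ids.append(0)  # right-pad short words to the kernel size
        return np.asarray(ids, dtype=np.intp)

    def entity_label_id(self, label: str) -> int:
        try:
            return self.entity_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown entity label {label!r}; schema must enumerate labels")


class CharCNN:
    """Character embedding + 1-D convolution + adaptive max pooling."""

    def __init__(self, vocab: Vocabulary, cfg: NetConfig, rng: np.random.Generator):
        d, k, nc = cfg.char_dim, cfg.kernel_size, cfg.channels
        self.cfg = cfg
        self.vocab = vocab
        self.char_table = ag.Parameter(ag.xavier_uniform(rng, len(vocab.chars), d, (len(vocab.chars), d)))
        self.W1 = ag.Parameter(ag.xavier_uniform(rng, k * d, nc, (nc, k * d)))
        self.b1 = ag.Parameter(np.zeros(nc))

    def parameters(self) -> list[Tensor]:
        return [self.char_table, self.W1, self.b1]

    def encode(self, word_text: str) -> Tensor:
        word_text = word_text.rstrip(PAD_CHAR)  # trailing pads never alter the code
        if not word_text:
            word_text = PAD_CHAR
        ids = self.vocab.char_ids(word_text, self.cfg.kernel_size)
        V = self.char_table.take_rows(ids)
        y = ag.conv1d_rows(V, self.W1, self.b1).leaky_relu()
        return y.max_over_rows()


class LSTMDirection:
    """One direction of an LSTM layer (combined gate weights)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.W_ih = ag.Parameter(ag.xavier_uniform(rng, in_dim, 4 * hidden, (4 * hidden, in_dim)))
        self.W_hh = ag.Parameter(ag.xavier_uniform(rng, hidden, 4 * hidden, (4 * hidden, hidden)))
        self.b = ag.Parameter(np.zeros(4 * hidden))

    def parameters(self) -> list[Tensor]:
        return [self.W_ih, self.W_hh, self.b]

    def run(self, xs: list[Tensor], reverse: bool = False) -> list[Tensor]:
        hd = self.hidden
        h = ag.constant(np.zeros(hd))
        c = ag.constant(np.zeros(hd))
        order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
        out: list[Tensor | None] = [None] * len(xs)
        for i in order:
            z = (self.W_ih @ xs[i]) + (self.W_hh @ h) + self.b
            gi = z.narrow(0, hd).sigmoid()
            gf = z.narrow(hd, 2 * hd).sigmoid()
            gg = z.narrow(2 * hd, 3 * hd).tanh()
            go = z.narrow(3 * hd, 4 * hd).sigmoid()
            c = gf * c + gi * gg
            h = go * c.tanh()
            out[i] = h
        return out  # type: ignore[return-value]


class BiLSTMLayer:
    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTMDirection(in_dim, hidden, rng)
        self.bwd = LSTMDirection(in_dim, hidden, rng)

    def parameters(self) -> list[Tensor]:
        return self.fwd.parameters() + self.bwd.parameters()

    def run(self, xs: list[Tensor]) -> list[Tensor]:
        f = self.fwd.run(xs)
        b = self.bwd.run(xs, reverse=True)
        return [ag.concat([f[i], b[i]]) for i in range(len(xs))]


@dataclass
class SentenceEncoding:
    """BiLSTM hidden sequence H and entity-label embedding sequence E."""

    H: list[Tensor]
    E: list[Tensor]
    tokens: list[Token] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.H)


class Encoder:
    """Shared sentence encoder feeding TR, RC and EE."""

    def __init__(self, vocab: Vocabulary, cfg: NetConfig, rng: np.random.Generator):
        self.vocab = vocab
        self.cfg = cfg
        self.word_table = ag.Parameter(
            ag.xavier_uniform(rng, len(vocab.words), cfg.word_dim, (len(vocab.words), cfg.word_dim))
        )
        self.entity_table = ag.Parameter(
            ag.xavier_uniform(rng, len(vocab.entity_labels), cfg.entity_dim,
                              (len(vocab.entity_labels), cfg.entity_dim))
        )
        self.char_cnn = CharCNN(vocab, cfg, rng) if cfg.use_char_cnn else None
        in_dim = cfg.word_dim + cfg.entity_dim + (cfg.channels if cfg.use_char_cnn else 0)
        self.layers: list[BiLSTMLayer] = []
        for layer in range(cfg.encoder_layers):
            self.layers.append(BiLSTMLayer(in_dim, cfg.hidden, rng))
            in_dim = 2 * cfg.hidden
        self.out_dim = 2 * cfg.hidden

    def parameters(self) -> list[Tensor]:
        params = [self.word_table, self.entity_table]
        if self.char_cnn is not None:
            params += self.char_cnn.parameters()
        for layer in self.layers:
            params += layer.parameters()
        return params

    def load_word_embeddings(self, table: np.ndarray) -> None:
        """Hook for pretrained word vectors (same shape as the word table)."""
        if table.shape != self.word_table.data.shape:
            raise ValueError(f"expected shape {self.word_table.data.shape}, got {table.shape}")
        self.word_table.data[...] = table

    def encode(
        self,
        tokens: list[Token],
        entity_labels: list[str],
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> SentenceEncoding:
        if len(tokens) != len(entity_labels):
            raise ValueError("one entity label per token required")
        word_ids = np.asarray([self.vocab.word_id(t.text) for t in tokens], dtype=np.intp)
        ent_ids = [self.vocab.entity_label_id(lbl) for lbl in entity_labels]
        W = self.word_table.take_rows(word_ids)
        E = [self.entity_table.row(i) for i in ent_ids]
        xs: list[Tensor] = []
        for i, tok in enumerate(tokens):
            parts = [W.row(i), E[i]]
            if self.char_cnn is not None:
                parts.append(self.char_cnn.encode(tok.text))
            xs.append(ag.concat(parts))
        H = xs
        for layer in self.layers:
            H = layer.run(H)
            if train and self.cfg.dropout > 0:
                assert rng is not None, "training dropout needs an rng"
                H = [h.dropout(self.cfg.dropout, rng) for h in H]
        return SentenceEncoding(H=H, E=E, tokens=list(tokens))


def entity_labels_for(tokens: list[Token], entities: list[EntityMention]) -> list[str]:
    """Per-token entity type labels ('O' for tokens outside any mention)."""
    labels = ["O"] * len(tokens)
    for ent in entities:
        for i, tok in enumerate(tokens):
            if tok.char_end > ent.char_start and tok.char_start < ent.char_end:
                if labels[i] == "O":
                    labels[i] = ent.entity_type
    return labels
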