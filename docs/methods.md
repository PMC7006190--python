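# Methods

## Task and data model

`bioevex` extracts biomedical events from sentence-level text in the
BioNLP-ST standoff convention: a document is a `.txt` file, an `.a1` file of
given entity mentions, and an `.a2` file of event triggers (`T` lines),
events (`E` lines, a typed trigger plus role-typed arguments) and
Negation/Speculation modifications (`M` lines). An argument filler may be an
entity or another event, so the gold annotation of a sentence is a directed
acyclic graph over triggers and entities. All character offsets are 0-based
half-open (brat convention). Extraction is restricted to single sentences:
cross-sentence annotations are dropped with a warning at read time, and a
word carries at most one trigger label (overlapping gold triggers keep the
first by file order).

Sentence splitting and tokenization are deliberately self-contained
rule-based procedures (no external NLP toolkit): sentences break at terminal
`[.?!]` followed by whitespace and a capital/digit/bracket, with a small
abbreviation exception list; tokens are whitespace chunks with leading and
trailing punctuation detached, keeping word-internal hyphens and slashes
intact because biomedical names depend on them. These exact rules are pinned
by fixtures; any rules with the same contracts (offsets reconstruct the
text, annotations fall inside sentences) would serve.

Trigger spans are encoded per token with BILOU labels (`B-`/`I-`/`L-`/`U-`
x event types, plus `O`). Decoding is total: orphan `I` opens a span like
`B`, orphan `L` acts like `U`, a span's type is fixed by its opening token,
and spans left open are closed at the previous token. Encode-then-decode is
the identity on every well-formed span set.

## Networks

All networks run on a compact tape-based reverse-mode autodiff module
(`bioevex.autograd`) operating on float64 numpy arrays, with Xavier-uniform
initialisation and an Adam optimizer (optional L2 weight decay folded into
the gradient). This keeps the package dependency-light and the arithmetic
bit-deterministic on CPU, at the cost of speed at scale — the intended
regime here is corpora of tens to hundreds of documents.

**Word representation.** Each token i is v_i = [w_i, e_i, ch_i]: a word
embedding, an embedding of the token's entity label (`O` for non-entities;
unknown labels are an error because the schema enumerates them), and a
character-level CNN feature: character embeddings convolved with kernel size
k and nc output channels (leaky-ReLU), then channel-wise max pooling so the
vector length is independent of word length. Words shorter than k are
right-padded with a reserved PAD character; trailing pads never change the
output. Embeddings are randomly initialised; a hook accepts pretrained word
vectors but none are required.

**Shared encoder.** A bidirectional LSTM over {v_i} yields
H = {h_1..h_n}, h_i = [forward h_i, backward h_i] (hidden size hd per
direction). The layer count is configurable (`encoder_layers`, default 1).
Dropout (default 0.5) is applied to LSTM outputs during training only.

**Trigger recognition (TR).** Greedy left-to-right labeling: at token i the
input is x_i = [h_i, t_{i-1}], where t_{i-1} embeds the previously assigned
label (a dedicated learned start vector at i = 0); two linear layers
(y = W3(f(W2 x + b2) + b3), leaky-ReLU f) and a log-softmax give p(t)_i.
The argmax non-O class m is assigned iff the support margin
s(t) = p(t)_m − p(t)_O exceeds `threshold_t`, else O; ties at the argmax go
to the lowest class index. Decoded multi-token triggers carry the arithmetic
mean of their tokens' margins as trigger-level support (mean rather than sum
so support is invariant to span length); the threshold is applied per token.
Training uses scheduled sampling with inverse sigmoid decay
eps = k/(k + exp(epoch/k)) (k = 10): the gold previous label is fed with
probability eps, the model's own assignment otherwise.

**Relation classification (RC).** Candidate pairs are all ordered
trigger→trigger and trigger→entity pairs within a sentence (no self-pairs;
both trigger-trigger directions, since nesting is directional). Each pair is
described by r = [src_max, mid_max, dst_max, d_v, dir]: adaptive max pooling
of the per-token [H, T, E] rows over the two spans; a convolution + max
pooling over the between-segment, replaced by a learned adjacency vector
when the spans touch (short segments are zero-padded to the kernel size); an
embedding of the token distance start2 − end1 clipped to [0, 30]; and a
binary flag marking pairs whose target precedes the source (slices are
always taken in text order). Two linear layers and a log-softmax give p(r);
the class margin over `none` is the support, thresholded by `threshold_r`.
A schema post-filter resets roles the source trigger's type cannot take to
`none` before event building.

**Event evaluation (EE).** For every detected trigger, all combinations of
its outgoing relations that satisfy the schema's per-role min/max counts
become candidate events, capped at 128 per trigger with highest-support
relations preferred. A candidate is rendered as a role-label sequence over
the sentence (`event_trigger` on trigger tokens, the role name on filler
tokens — for nested arguments, the sub-event trigger's tokens — `none_type`
elsewhere; precedence trigger > role > none on overlap), embedded, and
concatenated per token with [h_i, e_i, t_i]. A second BiLSTM runs over this
sequence; the concatenated final forward/backward states feed two
log-softmax heads: 2-class validity p(e) with support
s(e) = p(e)_valid − p(e)_invalid, and 3-class modification p(m) over
(Negation, Speculation, None). Nested candidates are enumerated at the
sub-event *trigger* level; the sub-event's own argument structure is
resolved by the combination strategy afterwards.

## Joint training

TR, RC, EE (validity and modification) each contribute a mean-reduced NLL;
the unweighted sum is back-propagated into the single shared encoder per
batch. The TR and RC terms weight non-none classes 5:1 against none. RC and
EE are teacher-forced during training (pairs from gold triggers, candidates
from gold triggers and relations; a candidate is positive iff its argument
set exactly matches a gold event's); per sentence, negative EE candidates
are undersampled to the positive count (at least one kept) to balance
classes. Defaults follow the tuned operating point: learning rate 0.007,
weight decay 0.0002, batch size 16, Adam, leaky-ReLU, thresholds
threshold_t = threshold_r = −2.0, 100 epochs, 5-member ensembles (members
differ only in seed). An ensemble predicts by arithmetically averaging
per-class log-probability vectors across members before any
support/threshold logic; the greedy TR decode is run jointly, each member
feeding its own embedding of the shared assigned label, so candidate sets
are identical across members by construction.

## Combination strategy (CS)

At prediction time the deliberately permissive thresholds (−2.0) hand a
superset of plausible triggers and relations to a global post-processor.
With weights alpha, beta, gamma ≥ 0 (defaults 0.5/0.25/0.125) the penalty of
a candidate subset c is

    penalty(c) = sum_{event in c} max(1 − alpha·s(e), 0)
               + beta  · sum_{uncovered triggers}  max(s(t), 0)
               + gamma · sum_{uncovered relations} max(s(r), 0)

— "support lacking" for chosen low-confidence events plus "support waste"
for confident triggers/relations no chosen event covers. Supports are
clamped at zero in the waste terms: only positive-support items generate
waste, otherwise discarding negative-support items would be rewarded in the
wrong direction. A trigger counts as covered when it is the trigger of a
chosen event or the nested filler of one; a relation when a chosen event
consumes it.

The exact argmin over subsets is exponential; it is implemented as a
brute-force oracle (guarded at |C| ≤ 20, ties toward smaller subsets then
lexicographic order) used for testing. Production selection is greedy
best-improvement: candidates are ordered topologically (sub-event triggers
before the candidates nesting them, cycles broken by dropping the edge
backed by the weakest relation support, input order preserved otherwise),
and starting from the empty set the admissible candidate with the largest
penalty decrease is added until none helps — O(|C|^2) penalty evaluations.
A candidate is admissible once each nested filler trigger already carries a
chosen event, which is how support flows between trigger groups. Two design
points resolved here: penalty-neutral candidates whose own lacking term is
zero (alpha·s(e) ≥ 1) are also admitted, since a fully confident event costs
nothing and dropping it would silently lose recall; and the greedy result's
penalty is re-checked against an independent evaluation on return.

After selection, events are instantiated children-first, a loop detector
adds them one by one and discards any event whose inclusion would close a
cycle (self-references included), dangling parents of discarded events are
pruned, and each event's modification is the argmax of p(m) with ties
resolved to None.

Ablation modes replace the selection step: `rule-single` keeps one maximal
candidate per trigger, `rule-all` keeps every candidate, `ee-probability`
keeps candidates whose trigger, relations and validity are all positive
(with thresholds at 0), and `zero-threshold` runs the CS with thresholds at
0.

## Evaluation

An event is a true positive only if trigger and full argument structure are
correct. Approximate span matching accepts a predicted trigger contained in
the gold span extended by one token on each side (same event type);
approximate recursive matching applies the same relaxation to event-valued
arguments recursively; `strict=True` demands exact spans. Predictions are
matched 1-1 greedily against gold; precision, recall and F1 are reported
overall and per event type (empty denominators give 0 by convention).
Unmatched predictions and missed gold events are decomposed into five
mutually exclusive categories with precedence: wrong trigger span (including
triggers absent from gold), wrong trigger label, redundant arguments (a
strict superset of a gold argument set on a correct trigger), wrong
arguments, other.

## Synthetic corpora

The generator emits schema-conforming standoff corpora, deterministic in the
seed, for development and testing without external downloads. Trigger and
entity words come from disjoint per-type lexicons (a type stem plus suffix,
e.g. `regulaoid`, `geneex`), so trigger recognition is learnable from word
identity and character shape; noise words and unused entities keep it
non-trivial. Each argument role is cued by its own connector word (`of`,
`by`, ...), making relation roles learnable from the between-segment;
modifications insert a cue word (`not`/`may`) before the trigger. Defaults:
2 sentences per document of 6–12 tokens, a top-level event in a sentence
with probability 0.85 (a second attempted at half that), nested fillers with
probability 0.35, modifications 0.15, two-token triggers 0.15. The default
toy schema has entity types Gene/Cancer, a flat Expression type
(entity Theme) and a nesting Regulation type (Theme + optional Cause, both
accepting events).

What this corpus does *not* emulate: lexical ambiguity between trigger
types, long-range arguments, discontinuous or cross-sentence structure,
real biomedical phrasing. Passing tests on it demonstrates that the
machinery — encoding, labeling, enumeration, penalty selection, standoff
round-tripping — is correct and that the joint model can fit and generalise
within this family, not that real-corpus accuracy is reproduced.

## Problem sizes and numerical choices

The test suite and the acceptance script train a single member with hd = 32
on 20 generated documents for 200 epochs (a few minutes on one CPU), which
drives event-level F1 to 1.0 on the training set and its held-out sibling
split; selection-oracle comparisons use 500 random instances with |C| ≤ 8
and supports ~ N(0, 2). Tie-breaks are deterministic everywhere (lowest
class index at argmax, None on modification ties, smaller subsets in the
oracle, input order in sorts). Degenerate inputs are defined: empty
sentences are skipped, words shorter than the char-CNN kernel are padded,
empty mid-segments use the adjacency vector, documents without entities
yield no events (every event ultimately grounds in an entity filler).

## Known limitations

Single-sentence scope and single-label triggers are inherited task
simplifications. The greedy selector is an approximation: on random
instances it matches the exact oracle in the large majority of cases but
can end one penalty step short of the optimum. Training is CPU-bound pure
Python/numpy and is not intended for shared-task-scale corpora; the
schema-driven enumeration caps candidates per trigger at 128, truncating
pathological relation fan-ins.
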