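# bioevex

Joint neural biomedical event extraction with a penalty-minimizing
combination strategy.

Biomedical events — "over-expression of *lamin* **promotes**
*tumorigenesis*" — are typed triggers with role-typed arguments whose
fillers may be entities or other events, forming nested structures.
`bioevex` extracts such events from BioNLP-ST standoff corpora
(`.txt`/`.a1`/`.a2`) end to end, for text-mining practitioners who want a
self-contained, dependency-light pipeline (numpy, pyyaml, click; no external
NLP toolkits, no deep-learning framework — the networks run on a small
autodiff module inside the package).

## Model

A shared sentence encoder feeds three heads trained jointly:

- **Encoder** — per token, v_i = [w_i, e_i, ch_i] (word embedding,
  entity-label embedding, character-CNN max-pooled feature), encoded by a
  BiLSTM into H = {h_i}.
- **Trigger recognition (TR)** — greedy left-to-right BILOU labeling over
  x_i = [h_i, t_{i−1}] with previous-label feedback and scheduled sampling
  ε = k/(k + e^{epoch/k}); a label is assigned when its support
  s^(t) = p^(t)_m − p^(t)_none exceeds threshold_t.
- **Relation classification (RC)** — every trigger→(trigger|entity) pair is
  scored from r = [src_max, mid_max, dst_max, d_v] (pooled span slices of
  [H, T, E], a conv+pooled between-segment, a clipped distance embedding);
  support s^(r) = p^(r)_m − p^(r)_none, thresholded by threshold_r.
- **Event evaluation (EE)** — schema-valid combinations of a trigger's
  relations become candidate events, rendered as role-label sequences and
  scored by a second BiLSTM: validity support s^(e) = p^(e)_1 − p^(e)_2 and
  a Negation/Speculation/None modification distribution p^(m).

Deliberately permissive thresholds (−2.0) pass a superset of candidates to
the **combination strategy**, which picks the final event set c ⊆ C by
(greedily, children-first over nested structure) minimizing

    penalty(c) = Σ_{event∈c} max(1 − α·s^(e), 0)
               + β·Σ_{uncovered triggers} max(s^(t), 0)
               + γ·Σ_{uncovered relations} max(s^(r), 0)

with α, β, γ = 0.5, 0.25, 0.125 — confident events cost nothing, confident
triggers/relations left unused cost "waste". A loop detector and
modification assignment finish the prediction. An exact brute-force solver
over all 2^|C| subsets serves as a testing oracle for the greedy selector.
Ensembles average per-class log-probabilities across members before any
thresholding. Scoring uses approximate span matching (gold span ± one
token) and approximate recursive matching of nested arguments.

## Worked example

A fully synthetic, schema-conforming corpus stands in for restricted-access
shared-task data (see `docs/methods.md` for what it does and does not
emulate):

```bash
bioevex simulate --n-docs 30 --seed 4 --out corpus
# wrote 18/6/6 train/dev/test documents to corpus

printf 'epochs: 80\nensemble_size: 1\nseed: 0\n' > config.yaml
bioevex train --corpus corpus/train --schema corpus/schema.yaml \
              --config config.yaml --out models
bioevex predict --models models --in corpus/test --out pred
# predicted 22 events over 6 documents
bioevex evaluate --gold corpus/test --pred pred
```

which prints:

```
overall: R=1.0000 P=0.8182 F1=0.9000 (gold=18, pred=22, tp=18)
  Expression: R=1.0000 P=1.0000 F1=1.0000
  Regulation: R=1.0000 P=0.6923 F1=0.8182
error breakdown (fraction of gold+spurious events):
  wrong_trigger_label: 0 (0.00%)
  wrong_trigger_span: 0 (0.00%)
  wrong_arguments: 4 (18.18%)
  redundant_arguments: 0 (0.00%)
  other: 0 (0.00%)
```

All 18 gold test events are recovered (recall 1.0); four spurious
Regulation events with wrong argument choices cost precision — exactly the
error class the combination strategy trades against recall. `--mode
rule-single|rule-all|ee-probability|zero-threshold` switches the selection
step to the rule-based or probability-based alternatives for comparison.
Per-epoch losses per head are logged to `models/loss_log.csv`.

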