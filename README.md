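# clinseg — sentence boundary disambiguation for clinical free text

Clinical notes break the assumptions general-English sentence splitters
rely on: section headers end in colons, list items and fragments end in
nothing at all, prose is hard-wrapped mid-sentence, and the text is dense
with abbreviations, dosages and vital signs whose periods and digits look
like boundaries.  `clinseg` treats sentence boundary disambiguation (SBD)
as sequence labeling: every token is tagged **B** (begins a sentence) or
**I** (sentence-internal), while tokens inside annotator-marked "Unsure"
regions (numeric tables, lab-value lines) are tagged **O** and masked out
of both training and evaluation.

The package is aimed at clinical-NLP practitioners who need a trainable,
institution-adaptable segmenter, and at anyone studying domain adaptation
for sequence labeling on private text: a synthetic note generator makes
the entire pipeline runnable and testable with no access to real EHR data.

## The model

For a token *w* with pretrained (or learned) word vector
**x**<sub>w</sub> ∈ ℝ³⁰⁰, a character CNN computes an *adjustment vector*
from the token's characters plus up to 7 raw characters of context on
each side (whitespace included — line breaks carry boundary evidence),
with marker symbols for word and document edges:

    a_w = MaxPool( Conv1D_{300 filters, width 4}( CharEmbed_30(chars(w)) ) )
    r_w = BatchNorm( x_w + a_w )

A bidirectional LSTM turns the word representations of a 32-token window
into contextual embeddings, and a sigmoid dense layer with L1-penalized
weights scores each token:

    h_t = BatchNorm( [ LSTM_fwd(r)_t ; LSTM_bwd(r)_t ] )
    p_t = sigmoid( w · h_t + b ),    tag B iff p_t ≥ 0.5

Training uses Adam on class-weighted binary cross-entropy — weights
w(c) = (1/2)/p(c) over the B/I distribution, so the rare B class is
penalized harder — with early stopping (patience 5) on validation loss.

Three **domain adaptation** strategies move a source-domain model to a
new institution's notes: *merged* training on both corpora, *continued*
training on the target corpus, and a *stacking ensemble* in which the
frozen source network's contextual embeddings are summed with those of a
freshly trained correction network before a shared prediction layer.
A character-window logistic-regression baseline (7 chars before / first 7
/ last 7 / 7 after each token) provides the maximum-entropy reference.

The whole network (char-CNN, bi-LSTM, batch norm, dropout, Adam,
backprop) is implemented in numpy inside the package (`clinseg.nn`) and
is verified against finite-difference gradients in the test suite.

## Worked example

```python
from clinseg import (SentenceSegmenter, corpus_to_xy, default_profiles,
                     generate_corpus, evaluate)
from clinseg.corpus import split_corpus

docs = generate_corpus(default_profiles()["mimic_like"], 200, seed=1234)
splits = split_corpus(docs, "cv_only", seed=1234)
x_train, y_train = corpus_to_xy(splits["train"])
x_val, y_val = corpus_to_xy(splits["validation"])

model = SentenceSegmenter(word_dim=50, char_dim=16, lstm_units=50,
                          max_epochs=15, random_state=1234)
model.fit(x_train, y_train, validation_data=(x_val, y_val))
report = evaluate(model.predict(x_val), y_val)
print(f"B-tag precision={report.b.precision:.3f} "
      f"recall={report.b.recall:.3f} F1={report.b.f1:.3f}")
```

Output:

```
B-tag precision=0.930 recall=0.987 F1=0.958
```

Read: on held-out synthetic ICU-style notes the reduced desk-scale model
finds 98.7% of true sentence starts, and 93.0% of predicted starts are
real — recall exceeding precision is the expected signature of the
class weighting, which penalizes a missed B far more than a spurious one.
The spans themselves come from `model.segment(text)`.

The same pipeline from the shell:

```bash
clinseg synth --profile mimic_like --n-docs 200 --seed 1234 --out notes/
clinseg stats --corpus notes/
clinseg train --corpus notes/ --seed 1234 --out model.npz
clinseg segment --checkpoint model.npz some_note.txt
```

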