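# Methods

## Problem and labeling scheme

Sentence boundary disambiguation on clinical notes is cast as per-token
binary sequence labeling.  Documents are tokenized by splitting on every
whitespace character, symbol and digit: a token is a maximal run of
letters or a single non-letter character, with character offsets kept so
the raw document is always recoverable.  Gold supervision comes from
character-span annotations: each "Sentence" span contributes a **B** tag
on its first contained token and **I** on the rest; tokens inside
"Unsure" spans (numeric tables, lab lines, metadata blocks) are **O**.
O positions are masked out of the loss and dropped from evaluation, so
the classifier only ever discriminates B from I; consequently every
false-positive B is a false-negative I and the two classes' scores are
symmetric.  B-tag precision/recall/F1, micro-averaged over all tokens,
is the primary metric.

Tokens outside every annotation are also treated as O.  The annotation
scheme only defines O for Unsure regions, but unannotated gaps are
equally un-evaluable, and O positions are masked everywhere, so this
choice cannot leak signal.  When a Sentence and an Unsure span overlap,
Unsure wins: low-confidence text should never contribute supervision.

## Architecture

Per token, the model sums a 300-d word vector with a 300-d *adjustment
vector* produced by a character CNN and batch-normalizes the result.
The CNN input is the token's own characters plus up to seven raw
characters of surrounding text on each side — whitespace preserved
verbatim, because blank lines, indentation and line breaks are exactly
what distinguishes headers, list items and wrapped prose — with marker
symbols for the end of the previous word, the beginning of the next
word, the word's own boundaries, and the document edges when they fall
inside the window.  Character embeddings are 30-d and learned during
tagging; the convolution has 300 filters of width 4 followed by global
max pooling.  The seven-character budget counts raw characters only;
markers ride along for free (the markers are insertions, not context).
Gap truncation keeps the seven characters nearest the focus token, where
the boundary evidence concentrates.

Word representations feed a bidirectional LSTM (default 200 units per
direction); the forward and backward states are concatenated and batch
normalized into contextual word embeddings.  Dropout (0.5 on LSTM
inputs) and variational recurrent dropout (0.25 on the hidden state,
mask fixed across time) regularize training; inference is deterministic.
A single sigmoid dense unit scores each contextual embedding; its
weights carry an L1 penalty (1e-5).  The sigmoid output is treated as
the probability that the token begins a sentence and thresholded at 0.5.

Pretrained word vectors (word2vec-format text, 300-d, trained on text
normalized by lowercasing, replacing symbols with spaces and spelling
digits out as English words) are supported with an all-zero fallback for
out-of-vocabulary tokens — deterministic, dimension-safe, and the
character pathway compensates.  When no vector file is supplied (all
synthetic experiments here), a word-embedding table of the same
dimension is learned from scratch.

## Training

Documents are cut into consecutive, non-overlapping 32-token windows
that never cross document boundaries (a bi-LSTM reading across unrelated
notes would learn spurious context); 32 windows form a mini-batch, with
the final short window padded and the padding masked.  The loss is
binary cross-entropy over unmasked positions, normalized by their count,
with class weights w(c) = (1/2)/p(c) computed from the training B/I
distribution — under the empirical distribution the expected weight is
exactly 1, so weighting rebalances the classes without rescaling the
loss.  Optimization is Adam (lr 0.001, β₁ 0.9, β₂ 0.999); training stops
after 5 epochs without a strictly lower validation loss and the
best-validation checkpoint is restored.  Character contexts are
precomputed per document; batch statistics for the two batch-norm layers
are taken over all window positions during training with momentum-0.9
running averages used at inference.

The entire network and its gradients are implemented in numpy
(`clinseg.nn`): embedding lookup, the width-4 convolution with
max-pooling, batch normalization, the LSTM (fused gates, forget-gate
bias 1, orthogonal recurrent initialization), the dense head, weighted
BCE and Adam.  Backpropagation is hand-derived and checked against
central finite differences in the test suite (`test_model.py`); at
max-pool ties the loss surface has kinks, so the check uses tie-free
character windows.  Everything is float64 and deterministic given the
seed on a single thread.

## Domain adaptation

Three strategies adapt a source-domain model to a target corpus, all
consuming identical document splits so comparisons are fair:

- **Merged training** — one model trained on the concatenated training
  splits, validated on the concatenated validation splits; vocabularies
  are built over the merged data and class weights derive from summed
  tag counts.
- **Continued training** — optimization of the source model resumes on
  the target corpus with a fresh Adam state and early stopping on target
  validation loss.  The pretrained weights enter the early-stopping
  comparison as the epoch “−1” candidate, so continuation can never
  return a checkpoint worse than its starting point.  Target-corpus
  symbols unseen by the source vocabularies map to UNK.
- **Stacking ensemble** — a freshly initialized tower (word
  representation + bi-LSTM) of identical dimensions is trained on the
  target corpus; its contextual embeddings are *summed* with those of
  the source tower before a shared, freshly initialized sigmoid head, so
  the new tower learns corrections to the source network.  The source
  tower is frozen by default (exposed as `freeze_base`): the correction
  framing presumes a fixed reference, and freezing makes the base
  reusable across targets.  The head is fresh rather than copied because
  it must weigh the summed representation, a different input
  distribution from either tower alone.  Vocabularies are the source
  model's extended in place (source ids stable); the frozen tower maps
  extensions through UNK.

## Synthetic study conditions

The synthetic generator produces the conditions all experiments run
under.  Each document is a sequence of units: prose sentences (10–24
words, hard-wrapped at a fixed column, so line breaks occur mid-sentence
as they do in real ICU notes), colon-terminated headers in ALL CAPS or
Title Case, un-terminated list items (2–5 words, optionally bulleted;
the bullet sits outside the gold span), `Label: value` lines, short
fragments, and numeric lab-table blocks carrying gold Unsure spans.
Prose is abbreviation- and number-dense ("b.i.d.", "120/80", "10 mg")
and contains mid-sentence capitalized tokens (drug names, surnames,
"Dr. Smith") so that neither "period + capital" nor "newline + capital"
is a reliable local cue — boundary decisions require knowing whether the
preceding line completed a unit, which is long-range information a
7-character window cannot see but a bi-LSTM can.  Sentence starts are
lowercase 40–50% of the time, as in hastily typed notes.

Two domain profiles are bundled.  `mimic_like` (ICU flavor) draws
termination types with probabilities matching the empirical ICU
distribution (25.4% of sentences end with no symbol, 53.7% with a
period, 20.5% with a colon); `fv_like` (outpatient flavor) uses the
outpatient distribution (53.8% no symbol, 31.2% period) plus a partially
disjoint vocabulary (60% overlap of the common pool; the rest
domain-unique words and pseudo-words), fewer bullets, fewer ALL-CAPS
headers and a wider wrap column.  The Unsure-block rates (0.14 / 0.035
of unit slots) put the O-token fractions in the neighborhood of the two
real corpora (29.1% and 8.5%), and the fraction is monotonically
controllable.  Generation is fully determined by the seed.

What passing tests on this data do and do not show: the generator
reproduces the *structural* ambiguities of clinical text (formatting,
termination mixes, abbreviation density, lexical shift between domains)
but none of its semantics — words are drawn independently from a pool,
so there is no grammar, no discourse structure, and no PHI-like content.
Results on it demonstrate that the architecture, losses, adaptation
mechanics and evaluation behave as designed, not that any particular F1
carries over to real notes.

## Desk-scale benchmarks

Two canned experiments (`clinseg.experiments`) size the problem for
CPU-minutes while preserving qualitative behavior.  The learning
benchmark trains a reduced model (50-d word/filter dimensions, 16-d
character embeddings, 50 LSTM units per direction, ≤15 epochs) against
the LR character-window baseline on 200 ICU-style documents with an
80/20 document split.  The adaptation benchmark trains on 100 ICU-style
documents and adapts to 80 outpatient-style documents (40-d/40-unit
model, ≤25 epochs, patience 5, three seeds); all three strategies are
scored on the same target validation split as the unadapted source
model.  The ensemble converges more slowly than continued training —
its correction tower and head start from scratch — which is why the
epoch cap is generous rather than tight.

## Numerical choices and edge cases

- Sigmoid probabilities are clipped to [1e-9, 1−1e-9] inside the loss.
- Character id sequences are padded to at least the convolution width
  with the PAD symbol (id 0, embedding pinned at zero); max-pooling over
  a window of pads yields the filter bias, identically for every token.
- Empty documents tokenize to empty sequences and predict to empty tag
  lists; an empty corpus is an error.
- Kappa is undefined when expected agreement is 1 (a single observed
  label); this raises rather than returning a sentinel.
- Splits are document-level and seeded; 100 documents give 80/20 under
  `cv_only` and 40/10/50 under `cv_plus_holdout`.
- Checkpoints are single `.npz` files embedding the configuration and
  both vocabularies, format-versioned.

## Known limitations

- Hyper-parameters that the original tuning left unstated (LSTM units,
  dropout rates, L1 strength, Adam settings) are exposed defaults, not
  tuned values.
- The LR baseline uses scikit-learn's LogisticRegression (lbfgs) rather
  than SGD on an equivalent one-unit dense layer; the decision function
  is identical.
- Subword inference for out-of-vocabulary words is not implemented; OOV
  word vectors are zero.
- Training is single-threaded numpy; full-size models (300-d, 200 units)
  train, but slowly — the package is sized for desk-scale experiments
  and method study, not production-scale corpora.
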