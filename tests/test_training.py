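"""Class weighting, batching geometry, loss masking and early stopping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinseg import nn
from clinseg.corpus import AnnotatedDocument, SpanAnnotation, to_bio
from clinseg.estimators import SentenceSegmenter
from clinseg.features import EncodedDocument
from clinseg.model import ModelConfig
from clinseg.training import (
    EarlyStopping,
    class_weights,
    evaluate_loss,
    make_batches,
    make_windows,
)

# ---------------------------------------------------------------------------
# Class weights


def test_equal_distribution_gives_unit_weights():
    assert class_weights({"B": 50, "I": 50}) == {"B": 1.0, "I": 1.0}


def test_weights_for_icu_corpus_tag_counts():
    # independent evaluation of w(c) = (1/2) / p(c) on the printed tallies
    counts = {"B": 23_648, "I": 200_272}
    total = sum(counts.values())
    expected = {c: 0.5 * total / n for c, n in counts.items()}
    got = class_weights(counts)
    assert got == pytest.approx(expected)
    assert got["B"] == pytest.approx(4.734, abs=5e-4)
    assert got["I"] == pytest.approx(0.559, abs=5e-4)
    assert got["B"] > got["I"]  # rarer class penalized harder


@given(
    st.integers(min_value=1, max_value=10**6),
    st.integers(min_value=1, max_value=10**6),
)
@settings(max_examples=200, deadline=None)
def test_expected_weight_under_empirical_distribution_is_one(b, i):
    w = class_weights({"B": b, "I": i})
    total = b + i
    assert (b / total) * w["B"] + (i / total) * w["I"] == pytest.approx(1.0, abs=1e-9)


def test_zero_count_is_an_error():
    with pytest.raises(ValueError):
        class_weights({"B": 0, "I": 10})


# ---------------------------------------------------------------------------
# Batching geometry


def _doc(n_tokens, labels=None, doc_id="d"):
    if labels is None:
        labels = np.zeros(n_tokens, dtype=np.int8)
    return EncodedDocument(
        doc_id,
        np.arange(2, 2 + n_tokens, dtype=np.int32) % 7 + 2,
        [[2, 3, 4, 5]] * n_tokens,
        np.asarray(labels, dtype=np.int8),
    )


def _config(**kw):
    base = dict(word_dim=4, char_dim=3, cnn_filters=4, lstm_units=3,
                sequence_length=32, batch_size=32, seed=0)
    base.update(kw)
    return ModelConfig(**base)


def test_seventy_token_document_cuts_into_32_32_6():
    batches = list(make_batches([_doc(70)], _config()))
    assert len(batches) == 1
    token_counts = batches[0].token_mask.sum(axis=1).tolist()
    assert token_counts == [32.0, 32.0, 6.0]
    # the short window's padding is masked out of the loss
    assert batches[0].mask[2, 6:].sum() == 0


def test_64_windows_make_two_batches():
    docs = [_doc(32, doc_id=str(i)) for i in range(64)]
    batches = list(make_batches(docs, _config()))
    assert [b.word_ids.shape[0] for b in batches] == [32, 32]


def test_windows_never_span_documents():
    docs = [_doc(40, doc_id="a"), _doc(10, doc_id="b")]
    windows = make_windows(docs, 32)
    assert windows == [(0, 0), (0, 32), (1, 0)]


def test_o_positions_are_masked_and_weighted_zero():
    labels = np.array([1, 0, -1, 0], dtype=np.int8)
    batch = next(iter(make_batches([_doc(4, labels)], _config(),
                                   weight_map={"B": 3.0, "I": 0.5})))
    assert batch.mask[0, 2] == 0.0
    assert batch.weights[0, 2] == 0.0
    assert batch.weights[0, 0] == 3.0
    assert batch.weights[0, 1] == 0.5
    assert batch.target[0].tolist()[:4] == [1.0, 0.0, 0.0, 0.0]


def test_shuffling_is_seed_deterministic():
    docs = [_doc(32, doc_id=str(i)) for i in range(10)]
    order1 = [b.windows for b in make_batches(docs, _config(), np.random.default_rng(5))]
    order2 = [b.windows for b in make_batches(docs, _config(), np.random.default_rng(5))]
    order3 = [b.windows for b in make_batches(docs, _config(), np.random.default_rng(6))]
    assert order1 == order2
    assert order1 != order3


def test_empty_corpus_is_an_error():
    with pytest.raises(ValueError):
        list(make_batches([], _config()))


# ---------------------------------------------------------------------------
# Loss


def test_weighted_loss_with_unit_weights_is_plain_bce(rng):
    prob = rng.uniform(0.05, 0.95, (3, 4))
    target = (rng.random((3, 4)) < 0.5).astype(float)
    mask = np.ones((3, 4))
    loss, _ = nn.weighted_bce(prob, target, np.ones((3, 4)), mask)
    plain = -np.mean(target * np.log(prob) + (1 - target) * np.log(1 - prob))
    assert loss == pytest.approx(plain)


def test_loss_ignores_masked_positions(rng):
    prob = rng.uniform(0.05, 0.95, (2, 5))
    target = (rng.random((2, 5)) < 0.5).astype(float)
    mask = np.ones((2, 5))
    mask[0, 1] = mask[1, 4] = 0.0
    weights = np.ones((2, 5)) * mask
    loss, dz = nn.weighted_bce(prob, target, weights, mask)
    perturbed = prob.copy()
    perturbed[0, 1] = 0.99
    perturbed[1, 4] = 0.01
    loss2, _ = nn.weighted_bce(perturbed, target, weights, mask)
    assert loss == pytest.approx(loss2)
    assert dz[0, 1] == 0.0 and dz[1, 4] == 0.0


# ---------------------------------------------------------------------------
# Early stopping


def test_early_stopping_keeps_best_and_stops_after_patience():
    stopper = EarlyStopping(patience=5)
    losses = [3.0, 2.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
    stopped_at = None
    for epoch, loss in enumerate(losses):
        stopper.update(epoch, loss)
        if stopper.should_stop:
            stopped_at = epoch
            break
    assert stopped_at == 7  # epochs 3..7 show no improvement
    assert stopper.best_epoch == 2
    assert stopper.best_loss == 1.0


def test_early_stopping_requires_strict_improvement():
    stopper = EarlyStopping(patience=2)
    assert stopper.update(0, 1.0)
    assert not stopper.update(1, 1.0)
    assert not stopper.update(2, 1.0)
    assert stopper.should_stop


# ---------------------------------------------------------------------------
# Training loop


def _toy_corpus():
    """Two tiny documents whose boundaries are perfectly cued."""
    docs = []
    for i, text in enumerate(["Plan:\nstart dose now.\nhold dose now.",
                              "Labs:\nrepeat exam now.\ncheck rate now."]):
        anns = []
        pos = 0
        for line in text.split("\n"):
            anns.append(SpanAnnotation("Sentence", pos, pos + len(line), line))
            pos += len(line) + 1
        docs.append(AnnotatedDocument(f"t{i}", text, anns))
    return docs


def test_training_converges_on_separable_toy_corpus():
    docs = _toy_corpus()
    seqs = [to_bio(d) for d in docs]
    x = [d.text for d in docs]
    y = [s.tags for s in seqs]
    est = SentenceSegmenter(
        word_dim=12, char_dim=8, lstm_units=8, dropout=0.0, recurrent_dropout=0.0,
        max_epochs=60, patience=60, learning_rate=5e-3, random_state=0,
    )
    est.fit(x, y, validation_data=(x, y))
    assert est.history_.epochs[-1]["train_loss"] < 0.05
    assert est.predict(x) == y


def test_identical_seeds_give_identical_first_epoch_losses(small_xy):
    x, y = small_xy
    kw = dict(word_dim=10, char_dim=6, lstm_units=6, max_epochs=1, patience=1,
              random_state=11)
    a = SentenceSegmenter(**kw).fit(x[:6], y[:6], validation_data=(x[6:8], y[6:8]))
    b = SentenceSegmenter(**kw).fit(x[:6], y[:6], validation_data=(x[6:8], y[6:8]))
    assert a.history_.epochs[0] == b.history_.epochs[0]
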