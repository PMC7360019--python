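"""Scikit-learn-style estimators for sentence boundary tagging.

``SentenceSegmenter`` is the char-CNN + bi-LSTM tagger; ``X`` is a list of
raw document strings and ``y`` a list of per-token B/I/O tag sequences
aligned with :func:`clinseg.tokenization.tokenize`.  O positions are
masked out of training and never predicted.  ``CharWindowLogisticBaseline``
is the maximum-entropy reference classifier over fixed character windows.
Both compose with sklearn model-selection utilities through
``get_params``/``set_params``.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from . import nn
from .corpus import AnnotatedDocument, to_bio
from .evaluation import SentenceSpan, sentence_spans_from_tags
from .features import (
    CHAR_SPECIALS,
    EncodedDocument,
    PAD,
    Vocab,
    WordVectorTable,
    build_char_vocab,
    build_word_vocab,
    encode_document,
    lr_baseline_features,
    word_key,
)
from .model import Head, ModelConfig, SBDNetwork, Tower, load_checkpoint, save_checkpoint
from .tokenization import Token, tokenize
from .training import class_weights, fit_network, make_batches, tag_counts

__all__ = [
    "SentenceSegmenter",
    "CharWindowLogisticBaseline",
    "corpus_to_xy",
]


def corpus_to_xy(docs: Sequence[AnnotatedDocument]) -> Tuple[List[str], List[List[str]]]:
    """Convert annotated documents to ``(X, y)`` for the estimators."""
    x, y = [], []
    for doc in docs:
        seq = to_bio(doc)
        x.append(doc.text)
        y.append(seq.tags)
    return x, y


def _validation_split(
    x: Sequence, y: Sequence, fraction: float, seed: int
) -> Tuple[list, list, list, list]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(x))
    n_val = max(1, round(fraction * len(x)))
    val_idx = set(order[:n_val].tolist())
    xt = [x[i] for i in range(len(x)) if i not in val_idx]
    yt = [y[i] for i in range(len(x)) if i not in val_idx]
    xv = [x[i] for i in val_idx]
    yv = [y[i] for i in val_idx]
    return xt, yt, xv, yv


class SentenceSegmenter(BaseEstimator):
    """Char-CNN-enriched bi-LSTM sentence boundary tagger.

    Parameters mirror :class:`clinseg.model.ModelConfig`; the published
    architecture's dimensions are the defaults.  Pass ``word_vectors``
    (path to a word2vec-format text file) to use fixed pretrained word
    embeddings; otherwise a word embedding table of ``word_dim`` is
    learned from the training corpus.

    Attributes (after ``fit``)
    --------------------------
    network_ : SBDNetwork
        The trained computational graph.
    char_vocab_, word_vocab_ : Vocab
    class_weights_ : dict
    history_ : TrainLog
    """

    def __init__(
        self,
        word_dim: int = 300,
        char_dim: int = 30,
        cnn_filters: Optional[int] = None,
        cnn_width: int = 4,
        context_chars: int = 7,
        lstm_units: int = 200,
        dropout: float = 0.5,
        recurrent_dropout: float = 0.25,
        l1: float = 1e-5,
        sequence_length: int = 32,
        batch_size: int = 32,
        max_epochs: int = 100,
        patience: int = 5,
        learning_rate: float = 1e-3,
        decision_threshold: float = 0.5,
        class_weighting: bool = True,
        validation_fraction: float = 0.2,
        word_vectors: Optional[str] = None,
        random_state: int = 0,
    ):
        self.word_dim = word_dim
        self.char_dim = char_dim
        self.cnn_filters = cnn_filters
        self.cnn_width = cnn_width
        self.context_chars = context_chars
        self.lstm_units = lstm_units
        self.dropout = dropout
        self.recurrent_dropout = recurrent_dropout
        self.l1 = l1
        self.sequence_length = sequence_length
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.learning_rate = learning_rate
        self.decision_threshold = decision_threshold
        self.class_weighting = class_weighting
        self.validation_fraction = validation_fraction
        self.word_vectors = word_vectors
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _config(self) -> ModelConfig:
        return ModelConfig(
            word_dim=self.word_dim,
            char_dim=self.char_dim,
            cnn_filters=self.cnn_filters if self.cnn_filters is not None else self.word_dim,
            cnn_width=self.cnn_width,
            context_chars=self.context_chars,
            lstm_units=self.lstm_units,
            dropout=self.dropout,
            recurrent_dropout=self.recurrent_dropout,
            l1=self.l1,
            sequence_length=self.sequence_length,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            learning_rate=self.learning_rate,
            decision_threshold=self.decision_threshold,
            class_weighting=self.class_weighting,
            seed=self.random_state,
        )

    def _encode(
        self, x: Sequence[str], y: Optional[Sequence[Sequence[str]]]
    ) -> List[EncodedDocument]:
        docs = []
        for idx, text in enumerate(x):
            tokens = tokenize(text)
            tags = list(y[idx]) if y is not None else None
            if tags is not None and len(tags) != len(tokens):
                raise ValueError(
                    f"document {idx}: {len(tags)} tags for {len(tokens)} tokens"
                )
            docs.append(
                encode_document(
                    text,
                    tokens,
                    tags,
                    self.char_vocab_,
                    self.word_vocab_,
                    self.context_chars,
                    doc_id=str(idx),
                )
            )
        return docs

    def fit(
        self,
        X: Sequence[str],
        y: Sequence[Sequence[str]],
        validation_data: Optional[Tuple[Sequence[str], Sequence[Sequence[str]]]] = None,
    ) -> "SentenceSegmenter":
        """Fit on documents ``X`` with aligned B/I/O tag sequences ``y``.

        Without explicit ``validation_data``, a document-level
        ``validation_fraction`` split (seeded by ``random_state``) provides
        the early-stopping signal.
        """
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        if validation_data is None:
            if len(X) < 2:
                raise ValueError("need at least 2 documents to hold out validation")
            x_train, y_train, x_val, y_val = _validation_split(
                list(X), list(y), self.validation_fraction, self.random_state
            )
        else:
            x_train, y_train = list(X), list(y)
            x_val, y_val = list(validation_data[0]), list(validation_data[1])

        config = self._config()
        tokenized = [(t, tokenize(t)) for t in x_train]
        self.char_vocab_ = build_char_vocab(tokenized)
        self.word_vocab_ = build_word_vocab([toks for _, toks in tokenized])

        fixed = None
        if self.word_vectors is not None:
            table = WordVectorTable.load(self.word_vectors, expected_dim=self.word_dim)
            fixed = np.zeros((len(self.word_vocab_), self.word_dim))
            for sym, idx in ((s, self.word_vocab_[s]) for s in self.word_vocab_.symbols):
                if sym not in CHAR_SPECIALS:
                    fixed[idx] = table.lookup(sym)

        rng = np.random.default_rng(self.random_state)
        tower = Tower(
            config, len(self.char_vocab_), len(self.word_vocab_), rng, word_vectors=fixed
        )
        head = Head(2 * config.lstm_units, rng)
        self.network_ = SBDNetwork([tower], [True], head, config)

        train_docs = self._encode(x_train, y_train)
        val_docs = self._encode(x_val, y_val)
        self.class_weights_ = (
            class_weights(tag_counts(train_docs))
            if self.class_weighting
            else {"B": 1.0, "I": 1.0}
        )
        self.history_ = fit_network(self.network_, train_docs, val_docs, config, rng)
        self.config_ = config
        return self

    # ------------------------------------------------------------------

    def _forward_corpus(self, docs: List[EncodedDocument]) -> List[np.ndarray]:
        """Per-document B probabilities, inference mode."""
        config = self.network_.config
        probs = [np.zeros(len(d.word_ids)) for d in docs]
        for batch in make_batches(docs, config, rng=None):
            p, _ = self.network_.forward(batch.word_ids, batch.char_ids, training=False)
            for row, (d_idx, start) in enumerate(batch.windows):
                n = int(batch.token_mask[row].sum())
                probs[d_idx][start : start + n] = p[row, :n]
        return probs

    def predict_proba(self, X: Sequence[str]) -> List[np.ndarray]:
        """Per-token probability that the token begins a sentence."""
        self._check_fitted()
        return self._forward_corpus(self._encode(X, None))

    def predict(self, X: Sequence[str]) -> List[List[str]]:
        """Per-token B/I tags (B iff probability >= decision_threshold)."""
        return [
            ["B" if p >= self.decision_threshold else "I" for p in doc_probs]
            for doc_probs in self.predict_proba(X)
        ]

    def segment(self, text: str) -> List[SentenceSpan]:
        """Sentence character spans for one document."""
        tags = self.predict([text])[0]
        return sentence_spans_from_tags(tokenize(text), tags)

    def score(self, X: Sequence[str], y: Sequence[Sequence[str]]) -> float:
        """B-tag F1 against gold tags (O positions excluded)."""
        from .evaluation import evaluate

        return evaluate(self.predict(X), y).b.f1

    # ------------------------------------------------------------------

    def save(self, path) -> Path:
        self._check_fitted()
        return save_checkpoint(
            path,
            self.network_,
            self.char_vocab_,
            self.word_vocab_,
            extra_meta={"estimator": self.get_params(), "log": self.history_.to_dict()},
        )

    @classmethod
    def load(cls, path) -> "SentenceSegmenter":
        network, char_vocab, word_vocab, extra = load_checkpoint(path)
        est = cls(**{k: v for k, v in extra.get("estimator", {}).items()})
        est.network_ = network
        est.char_vocab_ = char_vocab
        est.word_vocab_ = word_vocab
        est.config_ = network.config
        # prediction-time encoding must match the checkpoint, not the
        # constructor defaults
        est.context_chars = network.config.context_chars
        est.decision_threshold = network.config.decision_threshold
        return est

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted; call fit() or load()")


class CharWindowLogisticBaseline(BaseEstimator):
    """Maximum-entropy (logistic regression) boundary classifier.

    For every token, four windows of ``width`` characters — before the
    token, the first characters of the token, its last characters, and
    the characters after it — are one-hot encoded over a character
    vocabulary and scored by a sigmoid dense layer.  O-tagged tokens are
    excluded from fitting, mirroring the tagger's masking.
    """

    def __init__(
        self,
        width: int = 7,
        c: float = 1.0,
        class_weighting: bool = True,
        max_iter: int = 200,
        random_state: int = 0,
    ):
        self.width = width
        self.c = c
        self.class_weighting = class_weighting
        self.max_iter = max_iter
        self.random_state = random_state

    def _featurize(self, text: str, tokens: Sequence[Token]) -> np.ndarray:
        n_sym = len(self.char_vocab_)
        dim = 4 * self.width * n_sym
        rows = np.zeros((len(tokens), dim), dtype=np.float32)
        for i in range(len(tokens)):
            symbols = lr_baseline_features(text, tokens, i, self.width)
            for pos, sym in enumerate(symbols):
                rows[i, pos * n_sym + self.char_vocab_[sym]] = 1.0
        return rows

    def fit(self, X: Sequence[str], y: Sequence[Sequence[str]]) -> "CharWindowLogisticBaseline":
        tokenized = [(t, tokenize(t)) for t in X]
        self.char_vocab_ = build_char_vocab(tokenized)
        feats, labels = [], []
        for (text, tokens), tags in zip(tokenized, y):
            rows = self._featurize(text, tokens)
            for row, tag in zip(rows, tags):
                if tag == "O":
                    continue
                feats.append(row)
                labels.append(1 if tag == "B" else 0)
        x_mat = np.vstack(feats)
        y_vec = np.asarray(labels)
        weight = None
        if self.class_weighting:
            counts = {"B": int(y_vec.sum()), "I": int((1 - y_vec).sum())}
            w = class_weights(counts)
            weight = {1: w["B"], 0: w["I"]}
        self.clf_ = LogisticRegression(
            C=self.c,
            max_iter=self.max_iter,
            class_weight=weight,
            random_state=self.random_state,
        )
        self.clf_.fit(x_mat, y_vec)
        return self

    def predict_proba(self, X: Sequence[str]) -> List[np.ndarray]:
        out = []
        for text in X:
            tokens = tokenize(text)
            if not tokens:
                out.append(np.zeros(0))
                continue
            rows = self._featurize(text, tokens)
            out.append(self.clf_.predict_proba(rows)[:, 1])
        return out

    def predict(self, X: Sequence[str]) -> List[List[str]]:
        return [
            ["B" if p >= 0.5 else "I" for p in probs] for probs in self.predict_proba(X)
        ]

    def score(self, X: Sequence[str], y: Sequence[Sequence[str]]) -> float:
        from .evaluation import evaluate

        return evaluate(self.predict(X), y).b.f1
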