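"""Domain-adaptation strategies for the sentence boundary tagger.

A tagger trained on one clinical corpus degrades on notes from another
institution whose vocabulary and formatting habits differ.  Three
strategies adapt a source-domain model to a target corpus:

``train_merged``
    Train one model on the concatenation of both corpora's training and
    validation splits.
``continue_training``
    Resume optimization of the source model on the target corpus
    (optimizer state reinitialized, all weights trainable, early stopping
    on target validation loss).
``ensemble_stack``
    Stacking ensemble: the source tower is kept (frozen by default) and a
    freshly initialized tower of identical dimensions is trained on the
    target corpus; the two towers' contextual word representations are
    summed before a shared, freshly initialized sigmoid prediction layer,
    so the new tower learns corrections to the source network.
"""

from __future__ import annotations

import copy
from collections import Counter
from typing import Optional, Sequence, Tuple

import numpy as np

from .estimators import SentenceSegmenter
from .features import Vocab, word_key
from .model import Head, ModelConfig, SBDNetwork, Tower, save_checkpoint
from .tokenization import tokenize
from .training import fit_network

__all__ = [
    "train_merged",
    "continue_training",
    "ensemble_stack",
    "EnsembleSegmenter",
]

Corpus = Tuple[Sequence[str], Sequence[Sequence[str]]]


def train_merged(
    train_a: Corpus,
    val_a: Corpus,
    train_b: Corpus,
    val_b: Corpus,
    **params,
) -> SentenceSegmenter:
    """One model on the union of both corpora's cross-validation data.

    Vocabularies are built over the merged training data and class
    weights derive from the summed tag counts.  With an empty corpus B
    this degenerates to ordinary training on corpus A.
    """
    x_train = list(train_a[0]) + list(train_b[0])
    y_train = list(train_a[1]) + list(train_b[1])
    x_val = list(val_a[0]) + list(val_b[0])
    y_val = list(val_a[1]) + list(val_b[1])
    est = SentenceSegmenter(**params)
    return est.fit(x_train, y_train, validation_data=(x_val, y_val))


def continue_training(
    base: SentenceSegmenter,
    train_b: Corpus,
    val_b: Corpus,
    **overrides,
) -> SentenceSegmenter:
    """Resume training of a fitted model on a new corpus.

    The base model's vocabularies are kept: target-corpus symbols the
    source never saw map to UNK.  The Adam state is reinitialized and the
    pretrained weights remain the fallback checkpoint, so the returned
    model is never worse than ``base`` on the target validation loss.
    ``overrides`` may adjust training-loop settings (epochs, patience,
    learning rate, seed) but not the architecture.
    """
    base._check_fitted()
    adapted = copy.deepcopy(base)
    for key, value in overrides.items():
        if not hasattr(adapted, key):
            raise TypeError(f"unknown override {key!r}")
        setattr(adapted, key, value)
    config = adapted._config()
    adapted.network_.config = config
    for tower in adapted.network_.towers:
        tower.config = config
    rng = np.random.default_rng(config.seed)
    train_docs = adapted._encode(list(train_b[0]), list(train_b[1]))
    val_docs = adapted._encode(list(val_b[0]), list(val_b[1]))
    adapted.history_ = fit_network(
        adapted.network_, train_docs, val_docs, config, rng, include_initial=True
    )
    adapted.config_ = config
    return adapted


def _extend_vocab(base: Vocab, new_symbols: Counter) -> Vocab:
    """Base vocabulary plus unseen symbols appended (existing ids stable)."""
    known = set(base.symbols)
    extra = sorted(
        (s for s in new_symbols if s not in known),
        key=lambda s: (-new_symbols[s], s),
    )
    return Vocab(base.symbols + extra)


class EnsembleSegmenter(SentenceSegmenter):
    """Two-tower stacking ensemble built on a fitted source model.

    The source tower is frozen by default (its weights and batch-norm
    statistics are bit-identical before and after adaptation); only the
    new tower and the shared prediction layer are optimized on the target
    corpus.  The shared prediction layer is freshly initialized because it
    must weigh the *summed* representation, a different input
    distribution from either tower alone.  Vocabularies are the base
    model's extended with target-corpus additions; the frozen tower maps
    the additions through UNK.
    """

    def __init__(
        self,
        base: Optional[SentenceSegmenter] = None,
        freeze_base: bool = True,
        max_epochs: int = 100,
        patience: int = 5,
        learning_rate: float = 1e-3,
        decision_threshold: float = 0.5,
        class_weighting: bool = True,
        random_state: int = 0,
    ):
        self.base = base
        self.freeze_base = freeze_base
        self.max_epochs = max_epochs
        self.patience = patience
        self.learning_rate = learning_rate
        self.decision_threshold = decision_threshold
        self.class_weighting = class_weighting
        self.random_state = random_state

    def fit(
        self,
        X: Sequence[str],
        y: Sequence[Sequence[str]],
        validation_data: Optional[Corpus] = None,
    ) -> "EnsembleSegmenter":
        if self.base is None:
            raise ValueError("EnsembleSegmenter requires a fitted base model")
        self.base._check_fitted()
        base_cfg = self.base.network_.config
        config = ModelConfig(
            **{
                **base_cfg.to_dict(),
                "max_epochs": self.max_epochs,
                "patience": self.patience,
                "learning_rate": self.learning_rate,
                "decision_threshold": self.decision_threshold,
                "class_weighting": self.class_weighting,
                "freeze_base": self.freeze_base,
                "seed": self.random_state,
            }
        )
        self.context_chars = config.context_chars

        if validation_data is None:
            from .estimators import _validation_split

            x_train, y_train, x_val, y_val = _validation_split(
                list(X), list(y), 0.2, self.random_state
            )
        else:
            x_train, y_train = list(X), list(y)
            x_val, y_val = list(validation_data[0]), list(validation_data[1])

        char_counts: Counter = Counter()
        word_counts: Counter = Counter()
        for text in x_train:
            char_counts.update(text)
            word_counts.update(word_key(t.text) for t in tokenize(text))
        self.char_vocab_ = _extend_vocab(self.base.char_vocab_, char_counts)
        self.word_vocab_ = _extend_vocab(self.base.word_vocab_, word_counts)

        rng = np.random.default_rng(self.random_state)
        base_tower = self.base.network_.towers[0]
        if self.freeze_base:
            base_tower = copy.deepcopy(base_tower)
        new_tower = Tower(
            config, len(self.char_vocab_), len(self.word_vocab_), rng
        )
        head = Head(2 * config.lstm_units, rng)
        self.network_ = SBDNetwork(
            [base_tower, new_tower], [not self.freeze_base, True], head, config
        )

        train_docs = self._encode(x_train, y_train)
        val_docs = self._encode(x_val, y_val)
        self.history_ = fit_network(self.network_, train_docs, val_docs, config, rng)
        self.config_ = config
        return self

    def save(self, path):
        self._check_fitted()
        params = {k: v for k, v in self.get_params(deep=False).items() if k != "base"}
        return save_checkpoint(
            path,
            self.network_,
            self.char_vocab_,
            self.word_vocab_,
            extra_meta={"estimator": params, "log": self.history_.to_dict()},
        )


def ensemble_stack(
    base: SentenceSegmenter,
    train_b: Corpus,
    val_b: Corpus,
    **overrides,
) -> EnsembleSegmenter:
    """Train the stacking ensemble of a fitted source model on corpus B."""
    est = EnsembleSegmenter(base=base, **overrides)
    return est.fit(list(train_b[0]), list(train_b[1]), validation_data=val_b)
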