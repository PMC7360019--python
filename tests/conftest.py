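import numpy as np
import pytest

from clinseg import SentenceSegmenter, corpus_to_xy, default_profiles, generate_corpus
from clinseg.corpus import split_corpus

TINY_MODEL = dict(
    word_dim=12, char_dim=8, lstm_units=8, max_epochs=2, patience=2, random_state=0
)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_corpus(profiles):
    """A dozen ICU-style synthetic documents with gold annotations."""
    return generate_corpus(profiles["mimic_like"], 12, seed=3)


@pytest.fixture(scope="session")
def small_xy(small_corpus):
    return corpus_to_xy(small_corpus)


@pytest.fixture(scope="session")
def tiny_fitted(small_corpus):
    """A briefly trained tiny tagger, shared by checkpoint/ensemble tests."""
    splits = split_corpus(small_corpus, "cv_only", seed=3)
    x_train, y_train = corpus_to_xy(splits["train"])
    x_val, y_val = corpus_to_xy(splits["validation"])
    est = SentenceSegmenter(**TINY_MODEL)
    est.fit(x_train, y_train, validation_data=(x_val, y_val))
    return est


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
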