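"""Reproducible desk-scale benchmark harnesses.

Two canned experiments exercise the whole pipeline on synthetic corpora:
a within-domain learning benchmark (neural tagger vs the LR
character-window baseline on the ICU-style domain) and a cross-domain
adaptation benchmark (train on the ICU-style domain, adapt to the
outpatient-style domain with all three strategies, score on the target
validation split).  All strategies in the adaptation benchmark consume
identical document splits, so the comparison is fair by construction.

Problem sizes are desk-scale: corpora of one to two hundred short
synthetic notes and a reduced model (40-50 LSTM units per direction,
40-50-d embeddings) keep a full run in CPU-minutes while preserving the
qualitative behavior of the full-size architecture.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

from .adaptation import continue_training, ensemble_stack, train_merged
from .corpus import split_corpus
from .estimators import CharWindowLogisticBaseline, SentenceSegmenter, corpus_to_xy
from .evaluation import evaluate
from .synthetic import default_profiles, generate_corpus

__all__ = ["learning_benchmark", "adaptation_benchmark"]


def learning_benchmark(
    seed: int,
    n_docs: int = 200,
    word_dim: int = 50,
    char_dim: int = 16,
    lstm_units: int = 50,
    max_epochs: int = 15,
    patience: int = 5,
) -> Dict[str, float]:
    """Neural tagger vs LR baseline on one ICU-style synthetic corpus.

    Generates ``n_docs`` documents, splits them 80/20 at the document
    level, trains both models on the same training split and scores
    B-tag precision/recall/F1 on the held-out validation split.
    """
    profile = default_profiles()["mimic_like"]
    docs = generate_corpus(profile, n_docs, seed=seed)
    splits = split_corpus(docs, "cv_only", seed=seed)
    x_train, y_train = corpus_to_xy(splits["train"])
    x_val, y_val = corpus_to_xy(splits["validation"])
    neural = SentenceSegmenter(
        word_dim=word_dim,
        char_dim=char_dim,
        lstm_units=lstm_units,
        max_epochs=max_epochs,
        patience=patience,
        random_state=seed,
    ).fit(x_train, y_train, validation_data=(x_val, y_val))
    neural_report = evaluate(neural.predict(x_val), y_val)
    baseline = CharWindowLogisticBaseline(random_state=seed).fit(x_train, y_train)
    baseline_report = evaluate(baseline.predict(x_val), y_val)
    return {
        "neural_b_f1": neural_report.b.f1,
        "neural_b_precision": neural_report.b.precision,
        "neural_b_recall": neural_report.b.recall,
        "lr_b_f1": baseline_report.b.f1,
        "lr_b_precision": baseline_report.b.precision,
        "lr_b_recall": baseline_report.b.recall,
        "n_validation_tokens": float(neural_report.n_evaluated),
        "best_epoch": float(neural.history_.best_epoch),
    }


def adaptation_benchmark(
    seeds: Sequence[int],
    n_source: int = 100,
    n_target: int = 80,
    word_dim: int = 40,
    char_dim: int = 16,
    lstm_units: int = 40,
    max_epochs: int = 25,
    patience: int = 5,
) -> Dict[str, object]:
    """Cross-domain adaptation: ICU-style source, outpatient-style target.

    For each seed, trains a source model and evaluates on the target
    validation split unadapted, then adapts with merged training,
    continued training and the stacking ensemble, scoring each on the
    same target split.  Returns per-seed B-F1 lists and their means.
    """
    profiles = default_profiles()
    kw = dict(
        word_dim=word_dim,
        char_dim=char_dim,
        lstm_units=lstm_units,
        max_epochs=max_epochs,
        patience=patience,
    )
    per_seed: Dict[str, List[float]] = {
        "unadapted": [], "merged": [], "continued": [], "ensemble": []
    }
    for seed in seeds:
        source = generate_corpus(profiles["mimic_like"], n_source, seed=seed)
        target = generate_corpus(profiles["fv_like"], n_target, seed=seed + 1000)
        s_splits = split_corpus(source, "cv_only", seed=seed)
        t_splits = split_corpus(target, "cv_only", seed=seed)
        train_a = corpus_to_xy(s_splits["train"])
        val_a = corpus_to_xy(s_splits["validation"])
        train_b = corpus_to_xy(t_splits["train"])
        val_b = corpus_to_xy(t_splits["validation"])

        base = SentenceSegmenter(random_state=seed, **kw).fit(
            *train_a, validation_data=val_a
        )
        per_seed["unadapted"].append(evaluate(base.predict(val_b[0]), val_b[1]).b.f1)

        merged = train_merged(train_a, val_a, train_b, val_b, random_state=seed, **kw)
        per_seed["merged"].append(evaluate(merged.predict(val_b[0]), val_b[1]).b.f1)

        continued = continue_training(base, train_b, val_b, random_state=seed)
        per_seed["continued"].append(
            evaluate(continued.predict(val_b[0]), val_b[1]).b.f1
        )

        stacked = ensemble_stack(
            base, train_b, val_b, random_state=seed,
            max_epochs=max_epochs, patience=patience,
        )
        per_seed["ensemble"].append(evaluate(stacked.predict(val_b[0]), val_b[1]).b.f1)
    return {
        "per_seed": per_seed,
        "mean": {k: float(np.mean(v)) for k, v in per_seed.items()},
        "seeds": list(seeds),
    }
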