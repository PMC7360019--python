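"""Tag-level scoring with O-exclusion.

Positions whose gold tag is ``O`` (un-evaluable regions) are removed
before counting, after which every token is either B or I.  Precision,
recall and F1 are therefore symmetric between the classes: every false
positive B is a false negative I and vice versa.  B-tag scores are the
primary metric, being directly proportional to the accuracy of detected
sentence starts; I scores are computed but secondary.  Micro-averaged
over all tokens of all documents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

from .tokenization import Token

__all__ = ["EvalReport", "evaluate", "sentence_spans_from_tags", "SentenceSpan"]


@dataclass(frozen=True)
class ClassScores:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class EvalReport:
    """Per-class precision/recall/F1 plus confusion counts, O excluded."""

    b: ClassScores
    i: ClassScores
    n_evaluated: int

    def to_dict(self) -> dict:
        return {
            "B": vars(self.b),
            "I": vars(self.i),
            "n_evaluated": self.n_evaluated,
        }


def _prf(tp: int, fp: int, fn: int) -> ClassScores:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return ClassScores(precision, recall, f1, tp, fp, fn)


def evaluate(
    predicted: Sequence[Sequence[str]],
    gold: Sequence[Sequence[str]],
) -> EvalReport:
    """Score predicted against gold tag sequences.

    ``gold`` may contain O (dropped before counting); ``predicted`` holds
    only B/I.  Sequences must align pairwise in length.
    """
    if len(predicted) != len(gold):
        raise ValueError(
            f"corpus size mismatch: {len(predicted)} predicted vs {len(gold)} gold"
        )
    tp_b = fp_b = fn_b = tn_b = 0
    for seq_idx, (pred_seq, gold_seq) in enumerate(zip(predicted, gold)):
        if len(pred_seq) != len(gold_seq):
            raise ValueError(
                f"sequence {seq_idx}: length mismatch "
                f"({len(pred_seq)} predicted vs {len(gold_seq)} gold)"
            )
        for p, g in zip(pred_seq, gold_seq):
            if g == "O":
                continue
            if p not in ("B", "I"):
                raise ValueError(f"predicted tags must be B or I, got {p!r}")
            if g == "B":
                if p == "B":
                    tp_b += 1
                else:
                    fn_b += 1
            else:
                if p == "B":
                    fp_b += 1
                else:
                    tn_b += 1
    n = tp_b + fp_b + fn_b + tn_b
    # I-scores mirror B: TP(I)=TN(B), FP(I)=FN(B), FN(I)=FP(B)
    return EvalReport(
        b=_prf(tp_b, fp_b, fn_b),
        i=_prf(tn_b, fn_b, fp_b),
        n_evaluated=n,
    )


@dataclass(frozen=True)
class SentenceSpan:
    begin: int
    end: int
    headless: bool = False  # leading I-run with no initial B


def sentence_spans_from_tags(
    tokens: Sequence[Token], tags: Sequence[str]
) -> List[SentenceSpan]:
    """Reconstruct sentence character spans from B/I tags.

    Each maximal run starting at a B token yields one span from that
    token's begin to the last run token's end.  A leading I-run (no
    preceding B) forms a span flagged headless.
    """
    if len(tokens) != len(tags):
        raise ValueError("tokens and tags must have equal length")
    spans: List[SentenceSpan] = []
    start: int | None = None
    last_end = 0
    headless = False
    for tok, tag in zip(tokens, tags):
        if tag == "B" or (tag == "I" and start is None):
            if tag == "B" and start is not None:
                spans.append(SentenceSpan(start, last_end, headless))
                start = None
            if start is None:
                start = tok.begin
                headless = tag == "I"
        last_end = tok.end
    if start is not None:
        spans.append(SentenceSpan(start, last_end, headless))
    return spans
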