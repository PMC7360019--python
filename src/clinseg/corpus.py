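"""BRAT standoff corpus handling, B/I/O conversion and corpus statistics.

Gold sentence boundaries are annotated as character-offset "Sentence"
spans; regions the annotators could not confidently segment (numeric
tables, lab-value lines) carry an "Unsure" span.  Supervision is derived
by tokenizing the document and tagging the first token of every sentence
``B``, the remaining sentence tokens ``I``, and every token inside an
Unsure region ``O``.  O positions are masked out of both training and
evaluation downstream.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.metrics import cohen_kappa_score

from .tokenization import Token, tokenize

__all__ = [
    "SENTENCE",
    "UNSURE",
    "SpanAnnotation",
    "AnnotatedDocument",
    "TaggedSequence",
    "TagDistribution",
    "TerminationStats",
    "BratParseError",
    "AnnotationIntegrityError",
    "read_brat",
    "write_brat",
    "read_brat_directory",
    "write_brat_directory",
    "to_bio",
    "tag_distribution",
    "tag_distribution_from_counts",
    "termination_stats",
    "termination_stats_from_counts",
    "classify_termination",
    "cohens_kappa",
    "split_corpus",
    "write_conll",
]

SENTENCE = "Sentence"
UNSURE = "Unsure"

TERMINATION_TYPES = (
    "period",
    "exclamation",
    "question",
    "semicolon",
    "colon",
    "quotation",
    "none",
)

_TERMINATOR_MAP = {
    ".": "period",
    "!": "exclamation",
    "?": "question",
    ";": "semicolon",
    ":": "colon",
    '"': "quotation",
    "'": "quotation",
}


class BratParseError(ValueError):
    """A standoff line could not be parsed."""


class AnnotationIntegrityError(ValueError):
    """An annotation does not agree with the document text."""


@dataclass(frozen=True)
class SpanAnnotation:
    """A labeled character span: ``Sentence`` or ``Unsure``."""

    label: str
    begin: int
    end: int
    text: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.begin:
            raise ValueError(f"empty annotation span [{self.begin}, {self.end})")
        if self.label not in (SENTENCE, UNSURE):
            raise ValueError(f"unsupported annotation label {self.label!r}")


@dataclass
class AnnotatedDocument:
    """Document text plus its gold Sentence/Unsure spans."""

    doc_id: str
    text: str
    annotations: List[SpanAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ann in self.annotations:
            if ann.begin < 0 or ann.end > len(self.text):
                raise AnnotationIntegrityError(
                    f"{self.doc_id}: span [{ann.begin}, {ann.end}) outside document"
                )

    def spans(self, label: str) -> List[SpanAnnotation]:
        return [a for a in self.annotations if a.label == label]


@dataclass
class TaggedSequence:
    """Tokens of one document paired with B/I/O tags.

    ``text`` keeps the source document so character context can be built.
    """

    doc_id: str
    text: str
    tokens: List[Token]
    tags: List[str]

    def __post_init__(self) -> None:
        if len(self.tags) != len(self.tokens):
            raise ValueError("tags and tokens must have equal length")
        bad = set(self.tags) - {"B", "I", "O"}
        if bad:
            raise ValueError(f"invalid tags {bad}")


@dataclass(frozen=True)
class TagDistribution:
    counts: Dict[str, int]
    percentages: Dict[str, float]
    total: int


@dataclass(frozen=True)
class TerminationStats:
    counts: Dict[str, int]
    percentages: Dict[str, float]
    total: int


# ---------------------------------------------------------------------------
# BRAT standoff I/O


_TEXTBOUND = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")


def _normalize_ann_text(s: str) -> str:
    # BRAT cannot represent newlines inside the text column; spans crossing
    # line breaks store them as spaces.
    return s.replace("\r\n", " ").replace("\n", " ").replace("\r", " ")


def read_brat(ann_path, txt_path) -> AnnotatedDocument:
    """Read a paired ``.txt``/``.ann`` BRAT document.

    Only contiguous text-bound ("T") lines with Sentence/Unsure labels are
    consumed; other labels are skipped with a warning, and discontinuous
    (fragment) spans are rejected.  Each span's text column is checked
    against the covered document text (newlines normalized to spaces).
    """
    ann_path = Path(ann_path)
    txt_path = Path(txt_path)
    text = txt_path.read_text(encoding="utf-8")
    annotations: List[SpanAnnotation] = []
    for lineno, raw in enumerate(ann_path.read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip():
            continue
        if not raw.startswith("T"):
            # relations/events/attributes/notes: not part of this scheme
            continue
        m = _TEXTBOUND.match(raw)
        if m is None:
            if "\t" in raw and ";" in raw.split("\t")[1]:
                raise BratParseError(
                    f"{ann_path.name}:{lineno}: discontinuous spans are not supported"
                )
            raise BratParseError(f"{ann_path.name}:{lineno}: malformed text-bound line")
        _, label, begin_s, end_s, covered = m.groups()
        if label not in (SENTENCE, UNSURE):
            warnings.warn(
                f"{ann_path.name}:{lineno}: skipping annotation with label {label!r}",
                stacklevel=2,
            )
            continue
        begin, end = int(begin_s), int(end_s)
        if end > len(text) or begin < 0 or end <= begin:
            raise AnnotationIntegrityError(
                f"{ann_path.name}:{lineno}: span [{begin}, {end}) outside document"
            )
        actual = _normalize_ann_text(text[begin:end])
        if covered and actual != _normalize_ann_text(covered):
            raise AnnotationIntegrityError(
                f"{ann_path.name}:{lineno}: annotation text {covered!r} does not "
                f"match document text {actual!r}"
            )
        annotations.append(SpanAnnotation(label, begin, end, text[begin:end]))
    return AnnotatedDocument(txt_path.stem, text, annotations)


def write_brat(doc: AnnotatedDocument, out_dir) -> Tuple[Path, Path]:
    """Write ``doc`` as paired ``.txt``/``.ann`` files; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    txt_path = out_dir / f"{doc.doc_id}.txt"
    ann_path = out_dir / f"{doc.doc_id}.ann"
    txt_path.write_text(doc.text, encoding="utf-8")
    lines = []
    for i, ann in enumerate(sorted(doc.annotations, key=lambda a: (a.begin, a.end)), 1):
        covered = _normalize_ann_text(doc.text[ann.begin : ann.end])
        lines.append(f"T{i}\t{ann.label} {ann.begin} {ann.end}\t{covered}")
    ann_path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return txt_path, ann_path


def read_brat_directory(corpus_dir) -> List[AnnotatedDocument]:
    """Read every ``.txt``/``.ann`` pair under ``corpus_dir``, sorted by name."""
    corpus_dir = Path(corpus_dir)
    docs = []
    for txt_path in sorted(corpus_dir.glob("*.txt")):
        ann_path = txt_path.with_suffix(".ann")
        if not ann_path.exists():
            raise FileNotFoundError(f"missing annotation file for {txt_path.name}")
        docs.append(read_brat(ann_path, txt_path))
    if not docs:
        raise FileNotFoundError(f"no .txt/.ann pairs found in {corpus_dir}")
    return docs


def write_brat_directory(docs: Iterable[AnnotatedDocument], out_dir) -> Path:
    out_dir = Path(out_dir)
    for doc in docs:
        write_brat(doc, out_dir)
    return out_dir


# ---------------------------------------------------------------------------
# Span -> B/I/O conversion


def to_bio(doc: AnnotatedDocument, tokens: Optional[Sequence[Token]] = None) -> TaggedSequence:
    """Convert gold spans to per-token B/I/O tags.

    The first token contained in each Sentence span is tagged ``B`` and the
    rest ``I``; tokens inside Unsure spans are ``O``.  A token belongs to a
    span when its begin offset lies inside the span.  Tokens covered by
    both a Sentence and an Unsure span become ``O`` (low-confidence regions
    never contribute supervised signal), as do tokens outside every
    annotation.
    """
    if tokens is None:
        tokens = tokenize(doc.text)
    tags = ["O"] * len(tokens)
    unsure_ranges = [(a.begin, a.end) for a in doc.spans(UNSURE)]

    def in_unsure(tok: Token) -> bool:
        return any(b <= tok.begin < e for b, e in unsure_ranges)

    for span in sorted(doc.spans(SENTENCE), key=lambda a: a.begin):
        first = True
        for i, tok in enumerate(tokens):
            if span.begin <= tok.begin < span.end:
                if in_unsure(tok):
                    continue
                tags[i] = "B" if first else "I"
                first = False
    for i, tok in enumerate(tokens):
        if in_unsure(tok):
            tags[i] = "O"
    return TaggedSequence(doc.doc_id, doc.text, list(tokens), tags)


# ---------------------------------------------------------------------------
# Corpus statistics


def tag_distribution_from_counts(counts: Dict[str, int]) -> TagDistribution:
    """Tag distribution (counts and one-decimal percentages) from tallies."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty tag counts")
    percentages = {t: round(100.0 * c / total, 1) for t, c in counts.items()}
    return TagDistribution(dict(counts), percentages, total)


def tag_distribution(corpus: Iterable[TaggedSequence]) -> TagDistribution:
    counts: Dict[str, int] = {"B": 0, "I": 0, "O": 0}
    n_seq = 0
    for seq in corpus:
        n_seq += 1
        for tag in seq.tags:
            counts[tag] += 1
    if n_seq == 0:
        raise ValueError("empty corpus")
    return tag_distribution_from_counts(counts)


def classify_termination(sentence_text: str) -> str:
    """Termination type of a sentence: its final non-whitespace character."""
    stripped = sentence_text.rstrip()
    if not stripped:
        return "none"
    return _TERMINATOR_MAP.get(stripped[-1], "none")


def termination_stats_from_counts(counts: Dict[str, int]) -> TerminationStats:
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no sentences")
    full = {t: counts.get(t, 0) for t in TERMINATION_TYPES}
    percentages = {t: round(100.0 * c / total, 1) for t, c in full.items()}
    return TerminationStats(full, percentages, total)


def termination_stats(docs: Iterable[AnnotatedDocument]) -> TerminationStats:
    """Tally how gold sentences are terminated across ``docs``."""
    counts = {t: 0 for t in TERMINATION_TYPES}
    for doc in docs:
        for span in doc.spans(SENTENCE):
            counts[classify_termination(doc.text[span.begin : span.end])] += 1
    return termination_stats_from_counts(counts)


# ---------------------------------------------------------------------------
# Inter-annotator agreement


def cohens_kappa(
    tags_a: Sequence[str],
    tags_b: Sequence[str],
    exclude: Set[str] = frozenset(),
) -> float:
    """Chance-corrected agreement between two tag sequences.

    Positions where either sequence carries a label in ``exclude`` are
    dropped first (used to ignore ``O`` positions the way agreement is
    reported for sentence annotations).  Raises on length mismatch; raises
    ``ZeroDivisionError`` when expected agreement is 1 (kappa undefined).
    """
    if len(tags_a) != len(tags_b):
        raise ValueError(
            f"sequences differ in length ({len(tags_a)} vs {len(tags_b)})"
        )
    keep_a, keep_b = [], []
    for a, b in zip(tags_a, tags_b):
        if a in exclude or b in exclude:
            continue
        keep_a.append(a)
        keep_b.append(b)
    if not keep_a:
        raise ValueError("no positions left after exclusion")
    labels = sorted(set(keep_a) | set(keep_b))
    if len(labels) == 1:
        raise ZeroDivisionError(
            "kappa undefined: expected agreement is 1 (single label observed)"
        )
    return float(cohen_kappa_score(keep_a, keep_b, labels=labels))


# ---------------------------------------------------------------------------
# Train/validation/test splits


def split_corpus(
    docs: Sequence[AnnotatedDocument],
    scheme: str = "cv_only",
    seed: int = 0,
) -> Dict[str, List[AnnotatedDocument]]:
    """Deterministic document-level splits.

    ``cv_only``
        80% training / 20% validation (the cross-validation layout used for
        a source corpus).
    ``cv_plus_holdout``
        50% held out as an unseen test set; the remaining half split
        80/20 into training/validation (the target-corpus layout).

    Splitting is at the document level so a note never straddles splits.
    """
    docs = list(docs)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(docs))
    shuffled = [docs[i] for i in order]
    if scheme == "cv_only":
        if len(docs) < 2:
            raise ValueError("need at least 2 documents for an 80/20 split")
        n_val = max(1, round(0.2 * len(docs)))
        return {
            "train": shuffled[n_val:],
            "validation": shuffled[:n_val],
            "test": [],
        }
    if scheme == "cv_plus_holdout":
        if len(docs) < 4:
            raise ValueError("need at least 4 documents for a CV-plus-holdout split")
        n_test = len(docs) // 2
        rest = shuffled[n_test:]
        n_val = max(1, round(0.2 * len(rest)))
        return {
            "train": rest[n_val:],
            "validation": rest[:n_val],
            "test": shuffled[:n_test],
        }
    raise ValueError(f"unknown split scheme {scheme!r}")


def write_conll(sequences: Iterable[TaggedSequence], path) -> Path:
    """Write tagged corpora as two-column ``token<TAB>tag`` with blank lines
    between documents."""
    path = Path(path)
    blocks = []
    for seq in sequences:
        blocks.append(
            "\n".join(f"{tok.text}\t{tag}" for tok, tag in zip(seq.tokens, seq.tags))
        )
    path.write_text("\n\n".join(blocks) + "\n", encoding="utf-8")
    return path
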