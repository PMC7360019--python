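"""Character-context windows, vocabularies and word-vector lookup.

The character pathway of the tagger sees, for each token, the token's own
characters plus up to seven raw characters of surrounding text on each
side, with marker symbols for word and document boundaries.  Whitespace is
preserved verbatim inside the context: newlines, blank lines and
indentation carry most of the evidence for sentence boundaries in notes
that lack terminating punctuation.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .tokenization import DIGIT_NAMES, Token

__all__ = [
    "PAD",
    "UNK",
    "PREV_END",
    "NEXT_BEGIN",
    "WORD_BEGIN",
    "WORD_END",
    "DOC_BEGIN",
    "DOC_END",
    "CHAR_SPECIALS",
    "Vocab",
    "char_context",
    "build_char_vocab",
    "build_word_vocab",
    "word_key",
    "WordVectorTable",
    "lr_baseline_features",
    "encode_document",
    "EncodedDocument",
]

# Marker symbols; multi-character strings so they can never collide with a
# raw document character.
PAD = "<pad>"
UNK = "<unk>"
PREV_END = "<prev-end>"
NEXT_BEGIN = "<next-begin>"
WORD_BEGIN = "<w>"
WORD_END = "</w>"
DOC_BEGIN = "<doc>"
DOC_END = "</doc>"

CHAR_SPECIALS = (PAD, UNK, PREV_END, NEXT_BEGIN, WORD_BEGIN, WORD_END, DOC_BEGIN, DOC_END)


class Vocab:
    """Symbol -> contiguous integer id mapping; id 0 is PAD, id 1 is UNK.

    Construction order is deterministic (specials, then observed symbols by
    descending frequency with lexicographic tie-break) and the mapping
    round-trips bit-identically through JSON.
    """

    def __init__(self, symbols: Sequence[str]):
        if symbols[0] != PAD or symbols[1] != UNK:
            raise ValueError("vocab must start with PAD, UNK")
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate symbols in vocab")
        self._symbols = list(symbols)
        self._ids = {s: i for i, s in enumerate(symbols)}

    @classmethod
    def from_counts(cls, counts: Counter, specials: Sequence[str]) -> "Vocab":
        observed = sorted(
            (s for s in counts if s not in specials),
            key=lambda s: (-counts[s], s),
        )
        return cls(list(specials) + observed)

    def __len__(self) -> int:
        return len(self._symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._ids

    def __getitem__(self, symbol: str) -> int:
        return self._ids.get(symbol, 1)  # UNK fallback

    @property
    def symbols(self) -> List[str]:
        return list(self._symbols)

    def encode(self, symbols: Iterable[str]) -> List[int]:
        ids = self._ids
        return [ids.get(s, 1) for s in symbols]

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self._symbols, ensure_ascii=False), encoding="utf-8")
        return path

    @classmethod
    def load(cls, path) -> "Vocab":
        return cls(json.loads(Path(path).read_text(encoding="utf-8")))

    def __eq__(self, other) -> bool:
        return isinstance(other, Vocab) and self._symbols == other._symbols


def char_context(
    doc_text: str,
    tokens: Sequence[Token],
    index: int,
    budget: int = 7,
) -> List[str]:
    """Character-context window for ``tokens[index]``.

    Layout: ``[DOC_BEGIN?] [PREV_END?] [<=budget gap chars] WORD_BEGIN
    word-chars WORD_END [<=budget gap chars] [NEXT_BEGIN?] [DOC_END?]``.
    Gap truncation keeps the characters nearest the token.  PREV_END is
    present iff a previous token ends within ``budget`` characters of the
    token; DOC_BEGIN iff there is no previous token and the document start
    lies within the budget (symmetric on the right).  Markers are not
    counted against the character budget.
    """
    if not 0 <= index < len(tokens):
        raise IndexError(f"token index {index} out of range")
    tok = tokens[index]
    out: List[str] = []

    gap_begin = tokens[index - 1].end if index > 0 else 0
    left_gap = doc_text[gap_begin : tok.begin]
    if index > 0:
        if len(left_gap) <= budget:
            out.append(PREV_END)
    else:
        if len(left_gap) <= budget:
            out.append(DOC_BEGIN)
    out.extend(left_gap[-budget:] if budget else "")

    out.append(WORD_BEGIN)
    out.extend(tok.text)
    out.append(WORD_END)

    gap_end = tokens[index + 1].begin if index + 1 < len(tokens) else len(doc_text)
    right_gap = doc_text[tok.end : gap_end]
    out.extend(right_gap[:budget] if budget else "")
    if index + 1 < len(tokens):
        if len(right_gap) <= budget:
            out.append(NEXT_BEGIN)
    else:
        if len(right_gap) <= budget:
            out.append(DOC_END)
    return out


def word_key(token_text: str) -> str:
    """Canonical word-vocabulary key for a token (lowercased; digits keep
    their character form, symbols are their own keys)."""
    return token_text.lower()


def build_char_vocab(corpus: Iterable[Tuple[str, Sequence[Token]]]) -> Vocab:
    """Character vocabulary over every document character, plus markers.

    ``corpus`` yields ``(doc_text, tokens)`` pairs.
    """
    counts: Counter = Counter()
    empty = True
    for text, _tokens in corpus:
        empty = False
        counts.update(text)
    if empty:
        raise ValueError("empty corpus")
    return Vocab.from_counts(counts, CHAR_SPECIALS)


def build_word_vocab(corpus: Iterable[Sequence[Token]]) -> Vocab:
    """Word vocabulary over canonical token keys (frequency order)."""
    counts: Counter = Counter()
    empty = True
    for tokens in corpus:
        empty = False
        counts.update(word_key(t.text) for t in tokens)
    if empty:
        raise ValueError("empty corpus")
    return Vocab.from_counts(counts, (PAD, UNK))


class WordVectorTable:
    """Pretrained word vectors in word2vec text format.

    Lookup normalizes the token the same way the embedding corpus was
    preprocessed: lowercase, digits mapped to their English names; symbols
    have no entries.  Out-of-vocabulary tokens get a deterministic all-zero
    fallback (the character pathway compensates).
    """

    def __init__(self, vectors: Dict[str, np.ndarray], dim: int):
        self.dim = dim
        self._vectors = vectors
        self._zero = np.zeros(dim, dtype=np.float64)

    @classmethod
    def load(cls, path, expected_dim: Optional[int] = None) -> "WordVectorTable":
        path = Path(path)
        vectors: Dict[str, np.ndarray] = {}
        with path.open(encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(f"{path.name}: malformed word2vec header")
            _count, dim = int(header[0]), int(header[1])
            if expected_dim is not None and dim != expected_dim:
                raise ValueError(
                    f"{path.name}: table has {dim}-d vectors, expected {expected_dim}"
                )
            for lineno, line in enumerate(fh, 2):
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"{path.name}:{lineno}: expected {dim} values")
                vectors[parts[0]] = np.asarray(parts[1:], dtype=np.float64)
        return cls(vectors, dim)

    def lookup(self, token_text: str) -> np.ndarray:
        key = token_text.lower()
        if key in self._vectors:
            return self._vectors[key]
        if key in DIGIT_NAMES:
            name = DIGIT_NAMES[key]
            if name in self._vectors:
                return self._vectors[name]
        return self._zero


def lr_baseline_features(
    doc_text: str,
    tokens: Sequence[Token],
    index: int,
    width: int = 7,
) -> List[str]:
    """Fixed-length character windows for the logistic-regression baseline.

    Four windows of ``width`` symbols each: the characters before the
    token's begin, the first characters of the token, its last characters,
    and the characters after its end.  Short windows are PAD-filled;
    document edges contribute a DOC_BEGIN/DOC_END marker.
    """
    tok = tokens[index]
    before = list(doc_text[max(0, tok.begin - width) : tok.begin])
    if tok.begin < width:
        before = [DOC_BEGIN] + before
    before = [PAD] * (width - len(before)) + before[-width:]

    first = list(tok.text[:width])
    first = first + [PAD] * (width - len(first))
    last = list(tok.text[-width:])
    last = [PAD] * (width - len(last)) + last

    after = list(doc_text[tok.end : tok.end + width])
    if tok.end + width >= len(doc_text):
        after = after + [DOC_END]
    after = after[:width] + [PAD] * (width - len(after[:width]))
    return before + first + last + after


@dataclass
class EncodedDocument:
    """Integer-encoded view of one tagged document, ready for batching.

    ``labels`` holds 1 for B, 0 for I and -1 for O (masked).
    """

    doc_id: str
    word_ids: np.ndarray  # (n_tokens,) int32
    char_ids: List[List[int]]  # per-token char-context ids
    labels: np.ndarray  # (n_tokens,) int8


def encode_document(
    text: str,
    tokens: Sequence[Token],
    tags: Optional[Sequence[str]],
    char_vocab: Vocab,
    word_vocab: Vocab,
    context_chars: int = 7,
    doc_id: str = "",
) -> EncodedDocument:
    word_ids = np.asarray(
        [word_vocab[word_key(t.text)] for t in tokens], dtype=np.int32
    )
    char_ids = [
        char_vocab.encode(char_context(text, tokens, i, context_chars))
        for i in range(len(tokens))
    ]
    if tags is None:
        labels = np.zeros(len(tokens), dtype=np.int8)
    else:
        lab_map = {"B": 1, "I": 0, "O": -1}
        labels = np.asarray([lab_map[t] for t in tags], dtype=np.int8)
    return EncodedDocument(doc_id, word_ids, char_ids, labels)
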