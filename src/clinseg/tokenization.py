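"""Deterministic tokenization of clinical note text.

Clinical notes mix prose with headers, lab values and punctuation-dense
abbreviations, so the tokenizer is deliberately aggressive: text is split
whenever whitespace, a symbol or a digit is encountered.  A token is either
a maximal run of letters or exactly one non-letter, non-whitespace
character.  Offsets into the source document are preserved so that
character-level context can always be recovered from the original text.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

__all__ = ["Token", "tokenize", "normalize_for_embeddings", "DIGIT_NAMES"]

#: English names used when digits are spelled out for embedding training.
DIGIT_NAMES = {
    "0": "zero",
    "1": "one",
    "2": "two",
    "3": "three",
    "4": "four",
    "5": "five",
    "6": "six",
    "7": "seven",
    "8": "eight",
    "9": "nine",
}


@dataclass(frozen=True)
class Token:
    """A contiguous span of a document.

    Attributes
    ----------
    text : str
        The covered characters; either a maximal run of letters or a
        single symbol/digit.  Never contains whitespace.
    begin : int
        0-based inclusive character offset into the source document.
    end : int
        Exclusive character offset; ``doc[begin:end] == text``.
    """

    text: str
    begin: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.begin:
            raise ValueError(f"empty token span [{self.begin}, {self.end})")
        if not self.text:
            raise ValueError("token text must be non-empty")


def _is_letter(ch: str) -> bool:
    # Unicode letter category; EHR exports contain non-ASCII artifacts.
    return ch.isalpha()


def tokenize(text: str) -> List[Token]:
    """Split ``text`` on whitespace, symbols and digits.

    Runs of letters form one token each; every symbol and every digit is
    its own single-character token; whitespace produces no tokens.  The
    original text is exactly recoverable by interleaving token texts with
    the skipped characters.
    """
    tokens: List[Token] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif _is_letter(ch):
            j = i + 1
            while j < n and _is_letter(text[j]):
                j += 1
            tokens.append(Token(text[i:j], i, j))
            i = j
        else:
            tokens.append(Token(ch, i, i + 1))
            i += 1
    return tokens


def normalize_for_embeddings(text: str) -> str:
    """Normalize text the way the word-embedding corpus is preprocessed.

    Symbols become spaces, each digit 0-9 becomes its English name as a
    separate word, and letters are lowercased; the result contains only
    lowercase letters separated by single spaces.  Idempotent.

    >>> normalize_for_embeddings("1.23")
    'one two three'
    """
    parts: List[str] = []
    for ch in text:
        if _is_letter(ch):
            parts.append(ch.lower())
        elif ch in DIGIT_NAMES:
            parts.append(" " + DIGIT_NAMES[ch] + " ")
        else:
            parts.append(" ")
    return " ".join("".join(parts).split())
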