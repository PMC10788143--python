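"""Note selection, cleaning, tokenization and vectorization.

Selection keeps notes whose routing metadata mentions "social"
(case-insensitive) in the encounter type, department name, specialty or
provider type. Quality filtering removes notes under 30 characters and
exact duplicate texts. Tokenization lowercases, strips everything that
is not a letter, and removes English stop words from a packaged static
list so results do not drift with library versions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .corpus import DocTermMatrix, Note, Vocabulary

__all__ = [
    "load_stopwords",
    "select_social_notes",
    "filter_notes",
    "FilterCounts",
    "tokenize",
    "build_matrix",
]

MIN_NOTE_CHARS = 30

_NON_ALPHA = re.compile(r"[^a-z]+")


def load_stopwords() -> frozenset[str]:
    """The packaged English stop-word list (lowercase)."""
    text = (
        resources.files("sdohtopics").joinpath("data/stopwords.txt").read_text("utf-8")
    )
    return frozenset(w for w in text.split() if w)


_SOCIAL_FIELDS = ("encounter_type", "department_name", "specialty", "provider_type")


def select_social_notes(notes: Sequence[Note]) -> list[Note]:
    """Keep notes whose metadata contains the substring "social".

    The match is case-insensitive over the four routing fields; a
    missing field counts as empty. Order is preserved.
    """
    kept = []
    for n in notes:
        for f in _SOCIAL_FIELDS:
            if "social" in (getattr(n, f, "") or "").lower():
                kept.append(n)
                break
    return kept


@dataclass(frozen=True)
class FilterCounts:
    n_input: int
    n_short: int
    n_duplicate: int
    n_kept: int


def _normalize_endings(text: str) -> str:
    return text.replace("\r\n", "\n").replace("\r", "\n")


def filter_notes(notes: Sequence[Note]) -> tuple[list[Note], FilterCounts]:
    """Drop notes under 30 characters, then exact duplicate texts.

    The length rule is strict (< 30) on the raw text. Duplicates are
    exact string matches after normalizing line endings; the first
    occurrence is kept. Order is otherwise preserved. Idempotent.
    """
    long_enough = [n for n in notes if len(n.text) >= MIN_NOTE_CHARS]
    n_short = len(notes) - len(long_enough)
    seen: set[str] = set()
    kept: list[Note] = []
    for n in long_enough:
        key = _normalize_endings(n.text)
        if key not in seen:
            seen.add(key)
            kept.append(n)
    counts = FilterCounts(
        n_input=len(notes),
        n_short=n_short,
        n_duplicate=len(long_enough) - len(kept),
        n_kept=len(kept),
    )
    return kept, counts


def tokenize(text: str, stopwords: frozenset[str] | set[str] = frozenset()) -> list[str]:
    """Lowercase, strip non-letters, split, drop stop words.

    Tokens are maximal runs of ASCII letters after lowercasing; tabs,
    newlines and other whitespace act as separators along with every
    other non-letter character. Digits and punctuation are removed.
    """
    tokens = _NON_ALPHA.split(text.lower())
    return [t for t in tokens if t and t not in stopwords]


def build_matrix(token_lists: Sequence[Sequence[str]]) -> tuple[DocTermMatrix, Vocabulary]:
    """Count tokens into a sparse document-term matrix.

    The vocabulary is the sorted set of distinct tokens, so the same
    corpus always yields byte-identical matrices.
    """
    if not token_lists or all(len(t) == 0 for t in token_lists):
        raise ValueError("empty corpus: no tokens in any document")
    vocab = Vocabulary.from_tokens(token_lists)
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    for toks in token_lists:
        row: dict[int, int] = {}
        for t in toks:
            j = vocab.index[t]
            row[j] = row.get(j, 0) + 1
        for j in sorted(row):
            indices.append(j)
            data.append(row[j])
        indptr.append(len(indices))
    counts = sp.csr_matrix(
        (np.array(data, dtype=np.int64), np.array(indices), np.array(indptr)),
        shape=(len(token_lists), len(vocab)),
    )
    dtm = DocTermMatrix(counts, vocab, tuple(str(i) for i in range(len(token_lists))))
    return dtm, vocab


def tokenize_notes(
    notes: Iterable[Note], stopwords: frozenset[str] | None = None
) -> list[list[str]]:
    """Tokenize every note text with the packaged stop-word list."""
    if stopwords is None:
        stopwords = load_stopwords()
    return [tokenize(n.text, stopwords) for n in notes]
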