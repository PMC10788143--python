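"""Core data containers and IO for clinical note corpora.

Notes travel as JSON-lines (one record per line, UTF-8); the vectorized
corpus is a scipy sparse count matrix with a lexicographically ordered
vocabulary, exportable as MatrixMarket plus a plain-text word list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "Note",
    "Vocabulary",
    "DocTermMatrix",
    "read_notes_jsonl",
    "write_notes_jsonl",
]


@dataclass(frozen=True)
class Note:
    """One clinical note with its routing metadata.

    The four metadata strings (``encounter_type``, ``department_name``,
    ``specialty``, ``provider_type``) are the fields scanned for the
    substring "social" when selecting social work notes.
    """

    note_id: str
    patient_id: str
    text: str
    note_type: str = ""
    encounter_type: str = ""
    department_name: str = ""
    specialty: str = ""
    provider_type: str = ""
    icd10_codes: tuple[str, ...] = ()
    year: int = 0

    def __post_init__(self) -> None:
        # JSON round-trips lists; store codes immutably.
        if not isinstance(self.icd10_codes, tuple):
            object.__setattr__(self, "icd10_codes", tuple(self.icd10_codes))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["icd10_codes"] = list(self.icd10_codes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Note":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class Vocabulary:
    """Ordered word list with a word -> column-index map.

    Indices are 0-based, contiguous and bijective with the word list;
    the order is lexicographic so a given corpus always produces the
    same vocabulary.
    """

    words: tuple[str, ...]
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.words, tuple):
            object.__setattr__(self, "words", tuple(self.words))
        if not self.index:
            object.__setattr__(
                self, "index", {w: i for i, w in enumerate(self.words)}
            )
        if len(self.index) != len(self.words):
            raise ValueError("vocabulary words must be unique")

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def __getitem__(self, i: int) -> str:
        return self.words[i]

    @classmethod
    def from_tokens(cls, token_lists: Iterable[Sequence[str]]) -> "Vocabulary":
        seen: set[str] = set()
        for toks in token_lists:
            seen.update(toks)
        return cls(tuple(sorted(seen)))

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.words) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        words = Path(path).read_text(encoding="utf-8").splitlines()
        return cls(tuple(w for w in words if w))


@dataclass
class DocTermMatrix:
    """Sparse document-by-word count matrix.

    ``counts`` is CSR with nonnegative integer entries; ``note_ids`` maps
    rows back to notes. Row sums equal the token count of each cleaned
    document.
    """

    counts: sp.csr_matrix
    vocabulary: Vocabulary
    note_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if not isinstance(self.note_ids, tuple):
            self.note_ids = tuple(self.note_ids)
        d, v = self.counts.shape
        if d != len(self.note_ids):
            raise ValueError("row count does not match note_ids")
        if v != len(self.vocabulary):
            raise ValueError("column count does not match vocabulary")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_docs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_words(self) -> int:
        return self.counts.shape[1]

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def total_tokens(self) -> int:
        return int(self.counts.sum())

    def save(self, mtx_path: str | Path, vocab_path: str | Path) -> None:
        mmwrite(str(mtx_path), self.counts)
        self.vocabulary.save(vocab_path)

    @classmethod
    def load(
        cls,
        mtx_path: str | Path,
        vocab_path: str | Path,
        note_ids: Sequence[str] | None = None,
    ) -> "DocTermMatrix":
        counts = sp.csr_matrix(mmread(str(mtx_path)))
        vocab = Vocabulary.load(vocab_path)
        if note_ids is None:
            note_ids = tuple(str(i) for i in range(counts.shape[0]))
        return cls(counts, vocab, tuple(note_ids))


def read_notes_jsonl(path: str | Path) -> list[Note]:
    """Read one Note per line from a JSON-lines file."""
    notes: list[Note] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                notes.append(Note.from_dict(json.loads(line)))
    ids = [n.note_id for n in notes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate note_id in {path}")
    return notes


def write_notes_jsonl(notes: Iterable[Note], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(json.dumps(n.to_dict(), sort_keys=True) + "\n")


def iter_jsonl(path: str | Path) -> Iterator[dict]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield json.loads(line)
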