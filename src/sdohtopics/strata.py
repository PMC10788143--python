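"""Stratified analyses: ICD-10 chapters, topic proportions, word frequency.

Notes are stratified by note type and by the ten disease chapters of
the ICD-10 coding system exercised in the study (nervous, circulatory,
respiratory, digestive, musculoskeletal, genitourinary, pregnancy,
congenital, neoplasms, blood). Pooled label assignments become
per-category proportion rows; a one-vs-rest chi-squared test per
category ranks words whose frequencies differ most across strata.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import chi2 as _sklearn_chi2

from .corpus import DocTermMatrix, Note
from .labeling import UNLABELED, LabelAssignment, pool_runs

__all__ = [
    "ChapterMap",
    "load_chapter_map",
    "map_icd10_chapter",
    "notes_by_chapter",
    "topic_proportions",
    "chi2_word_selection",
    "word_frequency_heatmap",
]


@dataclass(frozen=True)
class ChapterMap:
    """Ordered (chapter, start, end) ranges over 3-character categories."""

    ranges: tuple[tuple[str, str, str], ...]

    def __iter__(self):
        return iter(self.ranges)

    def __len__(self) -> int:
        return len(self.ranges)

    @property
    def chapters(self) -> list[str]:
        return [name for name, _, _ in self.ranges]


def load_chapter_map(source: str | Path | None = None) -> ChapterMap:
    """Load the chapter ranges (packaged ten-chapter table by default)."""
    if source is None:
        text = (
            resources.files("sdohtopics")
            .joinpath("data/icd10_chapters.csv")
            .read_text("utf-8")
        )
    else:
        text = Path(source).read_text(encoding="utf-8")
    rows = list(csv.DictReader(text.splitlines()))
    ranges = tuple(
        (r["chapter"], r["start"].upper(), r["end"].upper()) for r in rows
    )
    return ChapterMap(ranges)


_DEFAULT_MAP: ChapterMap | None = None


def _default_map() -> ChapterMap:
    global _DEFAULT_MAP
    if _DEFAULT_MAP is None:
        _DEFAULT_MAP = load_chapter_map()
    return _DEFAULT_MAP


def map_icd10_chapter(code: str, chapter_map: ChapterMap | None = None) -> str | None:
    """Chapter containing an ICD-10 code's 3-character category, or None.

    The code is uppercased and truncated to its first three characters
    (letter + two alphanumerics); codes outside every range map to
    None. A malformed code (no leading letter, or shorter than three
    characters) maps to None with a warning.
    """
    if chapter_map is None:
        chapter_map = _default_map()
    if not code:
        raise ValueError("empty ICD-10 code")
    cat = code.strip().upper()[:3]
    if len(cat) < 3 or not cat[0].isalpha() or not all(c.isalnum() for c in cat[1:]):
        warnings.warn(f"malformed ICD-10 code {code!r}", stacklevel=2)
        return None
    for name, start, end in chapter_map:
        if start <= cat <= end:
            return name
    return None


def notes_by_chapter(
    notes: Sequence[Note], chapter_map: ChapterMap | None = None
) -> dict[str, list[Note]]:
    """Stratify notes by disease chapter.

    A note whose codes fall in several chapters contributes to each
    matching stratum; notes with no mappable code are excluded here
    (they remain in note-type strata).
    """
    if chapter_map is None:
        chapter_map = _default_map()
    strata: dict[str, list[Note]] = {name: [] for name in chapter_map.chapters}
    for n in notes:
        hit = set()
        for code in n.icd10_codes:
            ch = map_icd10_chapter(code, chapter_map)
            if ch is not None and ch not in hit:
                strata[ch].append(n)
                hit.add(ch)
    return strata


def topic_proportions(
    pooled: Mapping[str, Sequence[LabelAssignment]],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-category label-proportion matrix (rows sum to 1).

    ``pooled`` maps category -> label assignments pooled over replicate
    runs. Columns are the union of observed labels (or the given label
    list) plus the explicit "unlabeled" bucket.
    """
    if not pooled:
        raise ValueError("no categories to tabulate")
    per_cat = {cat: pool_runs(assigns, category=cat) for cat, assigns in pooled.items()}
    if labels is None:
        cols: set[str] = set()
        for props in per_cat.values():
            cols.update(props)
        cols.discard(UNLABELED)
        col_list = sorted(cols) + [UNLABELED]
    else:
        col_list = list(labels) + [UNLABELED]
    mat = pd.DataFrame(
        [[per_cat[cat].get(c, 0.0) for c in col_list] for cat in per_cat],
        index=list(per_cat),
        columns=col_list,
    )
    return mat


def chi2_word_selection(
    dtm: DocTermMatrix,
    category_labels: Sequence[str],
    stopwords: frozenset[str] | set[str] = frozenset(),
    top_n: int = 5,
) -> dict[str, list[tuple[str, float, float]]]:
    """Top discriminative words per category by one-vs-rest chi-squared.

    For every category the word counts are tested against the binary
    in-category indicator; words rank by ascending p-value (ties by
    descending statistic, then alphabetically). Stop words and words
    absent from the corpus are dropped. Returns
    category -> [(word, statistic, p_value), ...].
    """
    cats = sorted(set(category_labels))
    if len(cats) < 2:
        raise ValueError("need at least 2 categories")
    if len(category_labels) != dtm.n_docs:
        raise ValueError("one category label per document required")
    for c in cats:
        if sum(1 for x in category_labels if x == c) == 0:
            raise ValueError(f"category {c!r} has zero documents")
    X = dtm.counts
    vocab = dtm.vocabulary.words
    col_totals = np.asarray(X.sum(axis=0)).ravel()
    keep = np.array(
        [col_totals[j] > 0 and vocab[j] not in stopwords for j in range(len(vocab))]
    )
    labels_arr = np.asarray(category_labels)
    out: dict[str, list[tuple[str, float, float]]] = {}
    for c in cats:
        y = (labels_arr == c).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stats, pvals = _sklearn_chi2(X, y)
        order = sorted(
            (j for j in range(len(vocab)) if keep[j] and np.isfinite(stats[j])),
            key=lambda j: (pvals[j], -stats[j], vocab[j]),
        )
        out[c] = [(vocab[j], float(stats[j]), float(pvals[j])) for j in order[:top_n]]
    return out


def word_frequency_heatmap(
    dtm: DocTermMatrix,
    category_labels: Sequence[str],
    words: Sequence[str],
) -> pd.DataFrame:
    """Per-category frequency proportion of selected words.

    Entry (category, word) = count of the word in the category's
    documents / total tokens in the category.
    """
    cats = sorted(set(category_labels))
    labels_arr = np.asarray(category_labels)
    idx = dtm.vocabulary.index
    X = dtm.counts
    rows = []
    for c in cats:
        mask = labels_arr == c
        sub = X[np.where(mask)[0], :]
        total = sub.sum()
        counts = np.asarray(sub.sum(axis=0)).ravel()
        rows.append(
            [counts[idx[w]] / total if w in idx and total else 0.0 for w in words]
        )
    return pd.DataFrame(rows, index=cats, columns=list(words))
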