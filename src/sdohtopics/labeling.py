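"""Dictionary-based automatic topic labeling.

Each inferred topic is rendered as its top-word set and compared with a
curated dictionary of label -> keyword sets (one entry per
social-determinants theme, e.g. "Mental health", "Abuse history"). The
label with the largest intersection-over-union (IOU) against the topic's
word set wins, but only when at least 2 words overlap; otherwise the
topic stays unlabeled. Assignments from replicate runs are pooled into
label-proportion vectors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LabelDictionary",
    "LabelAssignment",
    "load_label_dictionary",
    "expand_dictionary",
    "assign_label",
    "pool_runs",
    "UNLABELED",
    "MIN_OVERLAP",
]

UNLABELED = "unlabeled"
MIN_OVERLAP = 2


@dataclass(frozen=True)
class LabelDictionary:
    """Mapping of label name -> lowercase keyword set."""

    labels: dict[str, frozenset[str]]
    provenance: str = "packaged"

    def __post_init__(self) -> None:
        for name, words in self.labels.items():
            if not words:
                raise ValueError(f"label {name!r} has an empty keyword set")
            for w in words:
                if not w or w != w.lower() or any(c.isspace() for c in w):
                    raise ValueError(
                        f"keyword {w!r} of label {name!r} must be a lowercase single token"
                    )

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.labels[name]

    def items(self):
        return self.labels.items()


def _reject_duplicate_keys(pairs):
    d: dict[str, object] = {}
    for k, v in pairs:
        if k in d:
            raise ValueError(f"duplicate label name {k!r} in dictionary file")
        d[k] = v
    return d


def load_label_dictionary(source: str | Path | None = None) -> LabelDictionary:
    """Load a label dictionary from JSON (label -> keyword array).

    With no argument, loads the packaged dictionary of 11
    social-determinants labels. Duplicate label names are an error;
    duplicate keywords within a label collapse into the set.
    """
    if source is None:
        text = (
            resources.files("sdohtopics")
            .joinpath("data/label_dictionary.json")
            .read_text("utf-8")
        )
        provenance = "packaged"
    else:
        text = Path(source).read_text(encoding="utf-8")
        provenance = str(source)
    raw = json.loads(text, object_pairs_hook=_reject_duplicate_keys)
    if not raw:
        raise ValueError("label dictionary is empty")
    labels = {name: frozenset(words) for name, words in raw.items()}
    return LabelDictionary(labels, provenance=provenance)


def expand_dictionary(
    dictionary: LabelDictionary,
    embeddings: Mapping[str, np.ndarray],
    n_neighbors: int,
    allow: Iterable[str] | None = None,
    deny: Iterable[str] = (),
) -> LabelDictionary:
    """Grow each keyword set with embedding nearest neighbors.

    For every keyword present in the embedding table, the ``n_neighbors``
    most cosine-similar other words are added to that label. Candidate
    words on the deny list are never added; if an allow list is given,
    only words on it may be added (this replaces a manual relevance
    review with an explicit, reproducible filter). Keywords missing from
    the embedding table are skipped with a warning. The input dictionary
    is not modified.
    """
    if n_neighbors < 0:
        raise ValueError("n_neighbors must be >= 0")
    deny_set = set(deny)
    allow_set = set(allow) if allow is not None else None
    if n_neighbors == 0:
        return LabelDictionary(dict(dictionary.labels), provenance="expanded")

    words = sorted(embeddings)
    mat = np.stack([np.asarray(embeddings[w], dtype=float) for w in words])
    norms = np.linalg.norm(mat, axis=1)
    norms[norms == 0] = 1.0
    unit = mat / norms[:, None]
    pos = {w: i for i, w in enumerate(words)}

    new_labels: dict[str, frozenset[str]] = {}
    for name, keys in dictionary.items():
        added: set[str] = set()
        for kw in sorted(keys):
            if kw not in pos:
                warnings.warn(
                    f"keyword {kw!r} of label {name!r} absent from embeddings; skipped",
                    stacklevel=2,
                )
                continue
            sims = unit @ unit[pos[kw]]
            # nearest neighbors excluding the query itself; ties by word order
            order = sorted(
                (i for i in range(len(words)) if i != pos[kw]),
                key=lambda i: (-sims[i], words[i]),
            )
            for i in order[:n_neighbors]:
                cand = words[i]
                if cand in deny_set:
                    continue
                if allow_set is not None and cand not in allow_set:
                    continue
                added.add(cand)
        new_labels[name] = frozenset(keys | added)
    return LabelDictionary(new_labels, provenance="expanded")


@dataclass(frozen=True)
class LabelAssignment:
    """Result of labeling one topic cluster."""

    run_id: int
    category: str
    topic: int
    label: str | None
    overlap: int
    union: int

    @property
    def iou(self) -> float:
        return self.overlap / self.union if self.union else 0.0


def assign_label(
    cluster_words: Iterable[str],
    dictionary: LabelDictionary,
    run_id: int = 0,
    category: str = "all",
    topic: int = 0,
) -> LabelAssignment:
    """Assign the max-IOU label to a topic's word set, or none.

    IOU(h) = |cluster ∩ keywords(h)| / |cluster ∪ keywords(h)|. The
    argmax label is assigned only when its overlap is at least 2 words.
    IOU comparisons use exact integer cross-multiplication; argmax ties
    break by lexicographic label name. Deterministic and invariant to
    top-word order.
    """
    cluster = frozenset(cluster_words)
    if not cluster:
        raise ValueError("cluster has no top words")
    best: tuple[int, int, str] | None = None  # (overlap, union, name)
    for name in sorted(dictionary):
        keys = dictionary[name]
        ov = len(cluster & keys)
        un = len(cluster | keys)
        if best is None or ov * best[1] > best[0] * un:
            best = (ov, un, name)
    assert best is not None
    ov, un, name = best
    if ov >= MIN_OVERLAP:
        return LabelAssignment(run_id, category, topic, name, ov, un)
    return LabelAssignment(run_id, category, topic, None, ov, un)


def pool_runs(
    assignments: Sequence[LabelAssignment], category: str | None = None
) -> dict[str, float]:
    """Pool replicate-run assignments into label proportions.

    Proportion of a label = clusters assigned that label across all runs
    / total clusters across all runs; unassigned clusters count in the
    explicit "unlabeled" bucket. Proportions sum to 1 and are invariant
    to run order.
    """
    if not assignments:
        raise ValueError("no assignments to pool")
    if category is not None:
        mismatched = {a.category for a in assignments} - {category}
        if mismatched:
            raise ValueError(f"assignments from other categories: {sorted(mismatched)}")
    counts: dict[str, int] = {}
    for a in assignments:
        key = a.label if a.label is not None else UNLABELED
        counts[key] = counts.get(key, 0) + 1
    total = len(assignments)
    return {k: counts[k] / total for k in sorted(counts)}
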