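"""Choosing the number of topics: coherence, redundancy, rank rule.

Topic coherence (C) is the sliding-window variant with one-set
segmentation and an indirect confirmation measure: word and word-pair
probabilities are estimated from boolean windows slid over each
document; each top word gets a vector of normalized pointwise mutual
information (NPMI) values against the full top-word set, and the topic
score is the mean cosine similarity between each word's vector and the
set's summed vector. Topic similarity (S) is the mean pairwise Jaccard
similarity of the topics' top-word sets; lower means less redundant.

For a grid of candidate topic counts, the K whose coherence rank i
(1 = highest C) plus similarity rank j (1 = smallest S) is minimal is
selected; ties on i + j break toward the smaller K.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .corpus import DocTermMatrix
from .lda import TopicModel, fit_lda, top_words

__all__ = [
    "WindowStats",
    "coherence",
    "jaccard",
    "topic_similarity",
    "KScanResult",
    "select_k",
    "rank_scan",
    "scan_k",
]

DEFAULT_WINDOW = 110
NPMI_EPS = 1e-12


class WindowStats:
    """Boolean sliding-window occurrence counts for a word universe.

    A document of length L contributes L - window + 1 windows when
    L > window, else a single window covering the whole document.
    """

    def __init__(
        self,
        corpus_tokens: Sequence[Sequence[str]],
        universe: Iterable[str],
        window: int = DEFAULT_WINDOW,
    ):
        if window < 2:
            raise ValueError("window must be >= 2")
        self.window = window
        self.universe = frozenset(universe)
        self.occurrence: Counter[str] = Counter()
        self.joint: Counter[frozenset[str]] = Counter()
        self.total_windows = 0
        uni = self.universe
        for doc in corpus_tokens:
            L = len(doc)
            if L == 0:
                continue
            if L <= window:
                spans = [doc]
            else:
                spans = [doc[i : i + window] for i in range(L - window + 1)]
            for span in spans:
                present = sorted(uni.intersection(span))
                self.total_windows += 1
                for w in present:
                    self.occurrence[w] += 1
                for a, b in itertools.combinations(present, 2):
                    self.joint[frozenset((a, b))] += 1
        if self.total_windows == 0:
            raise ValueError("corpus produced no windows")

    def p_word(self, w: str) -> float:
        return self.occurrence[w] / self.total_windows

    def p_pair(self, a: str, b: str) -> float:
        if a == b:
            return self.p_word(a)
        return self.joint[frozenset((a, b))] / self.total_windows

    def npmi(self, a: str, b: str) -> float:
        """NPMI in [-1, 1]; -1 for pairs that never co-occur."""
        pa, pb = self.p_word(a), self.p_word(b)
        if pa == 0.0 or pb == 0.0:
            # word absent from every window: epsilon probability
            pa = pa or NPMI_EPS
            pb = pb or NPMI_EPS
        pab = self.p_pair(a, b)
        if pab == 0.0:
            return -1.0
        if pab >= 1.0:
            return 1.0
        return math.log(pab / (pa * pb)) / (-math.log(pab))


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(u @ v / (nu * nv))


def coherence_from_stats(topic_top_words: Sequence[str], stats: WindowStats) -> float:
    """One-set-segmentation NPMI/cosine coherence from precomputed stats."""
    words = list(dict.fromkeys(topic_top_words))  # dedupe, order-free result
    if len(words) == 1:
        return 1.0
    missing = [w for w in words if stats.occurrence[w] == 0]
    if missing:
        warnings.warn(f"top words absent from all windows: {missing}", stacklevel=2)
    n = len(words)
    M = np.empty((n, n))
    for a in range(n):
        for b in range(n):
            M[a, b] = stats.npmi(words[a], words[b])
    v_set = M.sum(axis=0)
    return float(np.mean([_cosine(M[a], v_set) for a in range(n)]))


def coherence(
    topic_top_words: Sequence[str],
    corpus_tokens: Sequence[Sequence[str]],
    window: int = DEFAULT_WINDOW,
) -> float:
    """Coherence of one topic's top words against a tokenized corpus."""
    stats = WindowStats(corpus_tokens, topic_top_words, window)
    return coherence_from_stats(topic_top_words, stats)


def jaccard(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|A ∩ B| / |A ∪ B|; both sets empty is an error."""
    a, b = frozenset(set_a), frozenset(set_b)
    union = a | b
    if not union:
        raise ValueError("jaccard of two empty sets is undefined")
    return len(a & b) / len(union)


def topic_similarity(model_top_words: Sequence[Iterable[str]]) -> float:
    """Mean pairwise Jaccard similarity over all unordered topic pairs."""
    sets = [frozenset(w) for w in model_top_words]
    if len(sets) < 2:
        raise ValueError("topic similarity needs at least 2 topics")
    pairs = list(itertools.combinations(sets, 2))
    return float(np.mean([jaccard(a, b) for a, b in pairs]))


@dataclass(frozen=True)
class KScanResult:
    """Scores and ranks for one candidate topic count."""

    K: int
    C: float
    S: float
    i: int = 0  # rank of C, 1 = highest (competition ranking)
    j: int = 0  # rank of S, 1 = smallest


def rank_scan(scan: Sequence[KScanResult]) -> list[KScanResult]:
    """Fill in competition ranks: ties share the better rank."""
    if not scan:
        raise ValueError("empty scan")
    ranked = []
    for r in scan:
        i = 1 + sum(1 for o in scan if o.C > r.C)
        j = 1 + sum(1 for o in scan if o.S < r.S)
        ranked.append(replace(r, i=i, j=j))
    return ranked


def select_k(scan: Sequence[KScanResult]) -> int:
    """The K with the i-th highest C, j-th smallest S and minimal i + j.

    Ties on i + j break toward the smaller K. Invariant to the order of
    the scan list.
    """
    ranked = rank_scan(scan)
    best = min(ranked, key=lambda r: (r.i + r.j, r.K))
    return best.K


def scan_k(
    dtm: DocTermMatrix,
    corpus_tokens: Sequence[Sequence[str]],
    k_grid: Sequence[int],
    seeds: Sequence[int],
    n_top: int = 10,
    window: int = DEFAULT_WINDOW,
    **fit_kwargs,
) -> tuple[list[KScanResult], int, dict[int, list[TopicModel]]]:
    """Score every candidate K and pick one.

    For each K, one replicate fit per seed; C and S are averaged over
    replicates before ranking (C additionally over topics within a
    model). Returns (ranked scan, selected K, fitted models per K).
    """
    if not k_grid:
        raise ValueError("empty K grid")
    results = []
    models_by_k: dict[int, list[TopicModel]] = {}
    for K in k_grid:
        models = [fit_lda(dtm, K, seed=s, **fit_kwargs) for s in seeds]
        models_by_k[K] = models
        c_vals, s_vals = [], []
        for m in models:
            tops = [top_words(m, t, min(n_top, len(m.vocabulary))) for t in range(K)]
            stats = WindowStats(corpus_tokens, set().union(*map(set, tops)), window)
            c_vals.extend(coherence_from_stats(tw, stats) for tw in tops)
            if K >= 2:
                s_vals.append(topic_similarity(tops))
        results.append(
            KScanResult(K=K, C=float(np.mean(c_vals)),
                        S=float(np.mean(s_vals)) if s_vals else 0.0)
        )
    ranked = rank_scan(results)
    return ranked, select_k(results), models_by_k
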