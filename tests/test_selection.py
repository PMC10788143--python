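"""Coherence, Jaccard similarity and the K-selection rank rule."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sdohtopics.selection import (
    KScanResult,
    WindowStats,
    coherence,
    jaccard,
    rank_scan,
    select_k,
    topic_similarity,
)


def brute_force_coherence(top_words, docs, window):
    """Independent enumeration oracle: materialize every window as a set,
    count occurrences and pair co-occurrences, then apply the NPMI/cosine
    one-set confirmation measure."""
    words = list(dict.fromkeys(top_words))
    windows = []
    for doc in docs:
        if not doc:
            continue
        if len(doc) <= window:
            windows.append(set(doc))
        else:
            windows.extend(set(doc[i : i + window]) for i in range(len(doc) - window + 1))
    T = len(windows)
    p = {w: sum(1 for win in windows if w in win) / T for w in words}
    pj = {
        (a, b): sum(1 for win in windows if a in win and b in win) / T
        for a in words
        for b in words
    }

    def npmi(a, b):
        pa, pb = p[a] or 1e-12, p[b] or 1e-12
        pab = pj[(a, b)]
        if pab == 0:
            return -1.0
        if pab >= 1.0:
            return 1.0
        return math.log(pab / (pa * pb)) / (-math.log(pab))

    if len(words) == 1:
        return 1.0
    M = np.array([[npmi(a, b) for b in words] for a in words])
    v_set = M.sum(axis=0)

    def cos(u, v):
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        return 0.0 if nu == 0 or nv == 0 else float(u @ v / (nu * nv))

    return float(np.mean([cos(M[a], v_set) for a in range(len(words))]))


@pytest.fixture(scope="module")
def toy_corpus():
    """20 short documents with mixed co-occurrence structure."""
    rng = np.random.default_rng(42)
    vocab = [f"w{i}" for i in range(12)]
    docs = []
    for _ in range(20):
        length = int(rng.integers(4, 15))
        docs.append([vocab[i] for i in rng.integers(0, 12, size=length)])
    # force one pair to always co-occur and one word to appear alone
    docs.append(["w0", "w1"] * 3)
    docs.append(["w11"])
    return docs


class TestCoherence:
    def test_matches_brute_force_enumeration(self, toy_corpus):
        for words in (["w0", "w1", "w2"], ["w3", "w4", "w5", "w6", "w7"],
                      ["w0", "w11"]):
            for window in (3, 5, 110):
                ours = coherence(words, toy_corpus, window=window)
                oracle = brute_force_coherence(words, toy_corpus, window)
                assert ours == pytest.approx(oracle, abs=1e-9)

    def test_identical_context_vectors_score_one(self):
        # two words always together in every window -> identical NPMI
        # vectors -> every cosine is 1
        docs = [["a", "b", "c"] for _ in range(10)] + [["c", "d"]]
        assert coherence(["a", "b"], docs, window=5) == pytest.approx(1.0)

    def test_never_cooccurring_words_score_lower(self):
        docs = [["a", "b"]] * 10 + [["c", "d"]] * 10
        together = coherence(["a", "b"], docs, window=5)
        apart = coherence(["a", "c"], docs, window=5)
        assert apart < together

    def test_single_top_word_is_one_by_convention(self, toy_corpus):
        assert coherence(["w0"], toy_corpus) == 1.0

    def test_order_invariance(self, toy_corpus):
        a = coherence(["w0", "w3", "w5"], toy_corpus, window=5)
        b = coherence(["w5", "w0", "w3"], toy_corpus, window=5)
        assert a == pytest.approx(b, abs=1e-12)

    def test_absent_word_warns(self, toy_corpus):
        with pytest.warns(UserWarning, match="absent"):
            coherence(["w0", "zzz"], toy_corpus, window=5)

    def test_window_counting_convention(self):
        # doc shorter than window -> one window; longer -> L - w + 1
        stats = WindowStats([["a"] * 3], universe={"a"}, window=5)
        assert stats.total_windows == 1
        stats = WindowStats([["a"] * 7], universe={"a"}, window=5)
        assert stats.total_windows == 3


class TestJaccard:
    def test_identical_sets(self):
        s = set("abcdefghij")
        assert jaccard(s, set(s)) == 1.0

    def test_disjoint_sets(self):
        assert jaccard({"a", "b"}, {"c"}) == 0.0

    def test_reference_cluster_against_mental_health(self, reference_topics,
                                                     dictionary):
        """Top-10 of the first full-corpus topic vs the Mental health
        keywords: 3 shared words out of a 17-word union."""
        cluster = set(reference_topics[1])
        keys = dictionary["Mental health"]
        assert cluster & keys == {"anxiety", "depression", "mood"}
        assert len(cluster | keys) == 17
        assert jaccard(cluster, keys) == pytest.approx(3 / 17)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            jaccard(set(), set())

    @settings(derandomize=True, max_examples=100)
    @given(hst.sets(hst.sampled_from("abcdefgh")),
           hst.sets(hst.sampled_from("abcdefgh")))
    def test_symmetric_bounded_and_one_iff_equal(self, a, b):
        if not (a | b):
            return
        j = jaccard(a, b)
        assert j == jaccard(b, a)
        assert 0.0 <= j <= 1.0
        assert (j == 1.0) == (a == b)


class TestTopicSimilarity:
    def test_identical_topics(self):
        tops = [set("abcdefghij")] * 4
        assert topic_similarity(tops) == 1.0

    def test_disjoint_topics(self):
        tops = [{"a"}, {"b"}, {"c"}]
        assert topic_similarity(tops) == 0.0

    def test_mean_of_pairwise_jaccards(self):
        a = {"a", "b", "c", "d", "e"}
        b = {"a", "b", "f", "g", "h", "i", "j"}
        c = {"f", "k", "l", "m"}
        assert jaccard(a, b) == pytest.approx(0.2)
        assert jaccard(a, c) == 0.0
        assert jaccard(b, c) == pytest.approx(0.1)
        assert topic_similarity([a, b, c]) == pytest.approx(0.1)

    def test_fewer_than_two_topics_rejected(self):
        with pytest.raises(ValueError):
            topic_similarity([{"a"}])


def oracle_select(ks, cs, ss):
    """Exhaustive rank-enumeration oracle for the selection rule."""
    n = len(ks)
    best = None
    for idx in range(n):
        i = 1 + sum(1 for o in range(n) if cs[o] > cs[idx])
        j = 1 + sum(1 for o in range(n) if ss[o] < ss[idx])
        key = (i + j, ks[idx])
        if best is None or key < best[0]:
            best = (key, ks[idx])
    return best[1]


class TestSelectK:
    def test_single_candidate(self):
        assert select_k([KScanResult(K=15, C=0.4, S=0.2)]) == 15

    def test_worked_example(self):
        scan = [KScanResult(K=10, C=0.5, S=0.3),
                KScanResult(K=20, C=0.6, S=0.1),
                KScanResult(K=30, C=0.4, S=0.2)]
        ranked = {r.K: (r.i, r.j) for r in rank_scan(scan)}
        assert ranked == {10: (2, 3), 20: (1, 1), 30: (3, 2)}
        assert select_k(scan) == 20

    def test_exact_tie_prefers_smaller_k(self):
        scan = [KScanResult(K=30, C=0.5, S=0.2), KScanResult(K=10, C=0.5, S=0.2)]
        assert select_k(scan) == 10

    def test_order_invariance(self):
        scan = [KScanResult(K=k, C=c, S=s)
                for k, c, s in [(10, 0.3, 0.1), (20, 0.5, 0.3), (30, 0.4, 0.05)]]
        assert select_k(scan) == select_k(list(reversed(scan)))

    def test_randomized_against_enumeration_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(1, 9))
            ks = sorted(rng.choice(np.arange(2, 60), size=n, replace=False).tolist())
            # coarse grids force frequent ties
            cs = rng.choice([0.1, 0.2, 0.3, 0.4], size=n).tolist()
            ss = rng.choice([0.0, 0.05, 0.1], size=n).tolist()
            scan = [KScanResult(K=k, C=c, S=s) for k, c, s in zip(ks, cs, ss)]
            assert select_k(scan) == oracle_select(ks, cs, ss)

    def test_empty_scan_rejected(self):
        with pytest.raises(ValueError):
            select_k([])

    def test_competition_ranks_share_best_rank(self):
        scan = [KScanResult(K=10, C=0.5, S=0.1),
                KScanResult(K=20, C=0.5, S=0.2),
                KScanResult(K=30, C=0.4, S=0.2)]
        ranks = {r.K: (r.i, r.j) for r in rank_scan(scan)}
        assert ranks[10] == (1, 1)
        assert ranks[20] == (1, 2)  # tie on C shares rank 1
        assert ranks[30] == (3, 2)  # tie on S shares rank 2
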