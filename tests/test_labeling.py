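"""The label dictionary and the IOU topic-labeling heuristic."""

import json

import numpy as np
import pytest

from sdohtopics.labeling import (
    LabelDictionary,
    assign_label,
    expand_dictionary,
    load_label_dictionary,
    pool_runs,
)


class TestLoadDictionary:
    def test_packaged_dictionary_has_eleven_labels(self, dictionary):
        assert len(dictionary) == 11

    def test_mental_health_keywords(self, dictionary):
        assert dictionary["Mental health"] == frozenset(
            {"mental", "depression", "anxiety", "mood", "psychological",
             "physical", "cognitive", "emotional", "mind", "psychiatric"}
        )

    def test_duplicate_label_names_rejected(self, tmp_path):
        p = tmp_path / "dup.json"
        p.write_text('{"A": ["x", "y"], "A": ["z", "w"]}')
        with pytest.raises(ValueError, match="duplicate label"):
            load_label_dictionary(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.json"
        p.write_text("{}")
        with pytest.raises(ValueError, match="empty"):
            load_label_dictionary(p)

    def test_empty_keyword_set_rejected(self):
        with pytest.raises(ValueError, match="empty keyword"):
            LabelDictionary({"A": frozenset()})

    def test_non_lowercase_keyword_rejected(self):
        with pytest.raises(ValueError, match="lowercase"):
            LabelDictionary({"A": frozenset({"Mixed"})})


class TestExpandDictionary:
    @pytest.fixture
    def toy_embeddings(self):
        return {
            "depression": np.array([1.0, 0.0, 0.0]),
            "depressed": np.array([0.9, 0.1, 0.0]),
            "sadness": np.array([0.7, 0.3, 0.0]),
            "banana": np.array([0.0, 0.0, 1.0]),
        }

    @pytest.fixture
    def tiny_dict(self):
        return LabelDictionary({"Mood": frozenset({"depression"})})

    def test_zero_neighbors_is_identity(self, tiny_dict, toy_embeddings):
        out = expand_dictionary(tiny_dict, toy_embeddings, 0)
        assert out.labels == tiny_dict.labels
        assert out.provenance == "expanded"

    def test_nearest_neighbor_added(self, tiny_dict, toy_embeddings):
        # brute-force cosine over the toy table puts "depressed" first
        out = expand_dictionary(tiny_dict, toy_embeddings, 1)
        assert out["Mood"] == frozenset({"depression", "depressed"})

    def test_deny_list_blocks_candidate(self, tiny_dict, toy_embeddings):
        out = expand_dictionary(tiny_dict, toy_embeddings, 1, deny={"depressed"})
        assert "depressed" not in out["Mood"]

    def test_allow_list_restricts_candidates(self, tiny_dict, toy_embeddings):
        out = expand_dictionary(tiny_dict, toy_embeddings, 3, allow={"sadness"})
        assert out["Mood"] == frozenset({"depression", "sadness"})

    def test_missing_keyword_warns_and_skips(self, toy_embeddings):
        d = LabelDictionary({"X": frozenset({"notinvocab"})})
        with pytest.warns(UserWarning, match="absent"):
            out = expand_dictionary(d, toy_embeddings, 2)
        assert out["X"] == frozenset({"notinvocab"})

    def test_original_untouched(self, tiny_dict, toy_embeddings):
        before = dict(tiny_dict.labels)
        expand_dictionary(tiny_dict, toy_embeddings, 2)
        assert tiny_dict.labels == before


def brute_force_best_label(cluster, dictionary):
    """Independent oracle: exhaustive IOU over every label with Fraction
    arithmetic."""
    from fractions import Fraction

    cluster = set(cluster)
    scored = []
    for name in dictionary:
        keys = dictionary[name]
        ov = len(cluster & keys)
        scored.append((Fraction(ov, len(cluster | keys)), ov, name))
    best = min(scored, key=lambda t: (-t[0], t[2]))
    return best if best[1] >= 2 else None


class TestAssignLabel:
    def test_reference_cluster_gets_mental_health(self, reference_topics,
                                                  dictionary):
        a = assign_label(reference_topics[1], dictionary)
        assert a.label == "Mental health"
        assert a.overlap == 3 and a.union == 17
        assert a.iou == pytest.approx(3 / 17)
        # beats the runner-up with 2 shared words in a 23-word union
        keys = dictionary["Clinician/hospital/medication"]
        assert len(set(reference_topics[1]) & keys) == 2
        assert len(set(reference_topics[1]) | keys) == 23

    def test_agrees_with_brute_force_over_reference_clusters(
        self, reference_topics, dictionary
    ):
        for cluster in reference_topics.values():
            a = assign_label(cluster, dictionary)
            oracle = brute_force_best_label(cluster, dictionary)
            if oracle is None:
                assert a.label is None
            else:
                assert a.label == oracle[2]
                assert a.iou == pytest.approx(float(oracle[0]))

    def test_single_word_overlap_everywhere_gives_none(self, dictionary):
        # one word from each of several labels: every overlap is exactly 1
        cluster = ["mental", "family", "group", "suicide", "shelter"]
        for name in dictionary:
            assert len(set(cluster) & dictionary[name]) <= 1
        assert assign_label(cluster, dictionary).label is None

    def test_cluster_equal_to_keyword_set_scores_one(self, dictionary):
        cluster = sorted(dictionary["Insurance/income"])
        a = assign_label(cluster, dictionary)
        assert a.label == "Insurance/income" and a.iou == 1.0

    def test_invariant_to_word_order(self, reference_topics, dictionary):
        words = list(reference_topics[1])
        a = assign_label(words, dictionary)
        b = assign_label(list(reversed(words)), dictionary)
        assert (a.label, a.overlap, a.union) == (b.label, b.overlap, b.union)

    def test_iou_bounded_by_size_ratio(self, reference_topics, dictionary):
        for cluster in reference_topics.values():
            for name in dictionary:
                keys = dictionary[name]
                bound = min(len(set(cluster)), len(keys)) / max(
                    len(set(cluster)), len(keys)
                )
                a = assign_label(cluster, LabelDictionary({name: keys}))
                assert a.iou <= bound + 1e-12

    def test_empty_cluster_rejected(self, dictionary):
        with pytest.raises(ValueError):
            assign_label([], dictionary)


class TestPoolRuns:
    def _assignment(self, label, run_id=0, category="all", topic=0):
        from sdohtopics.labeling import LabelAssignment

        return LabelAssignment(run_id, category, topic, label, 2 if label else 1, 10)

    def test_counting(self):
        assigns = [self._assignment("Family") for _ in range(10)]
        assigns += [self._assignment(None) for _ in range(90)]
        props = pool_runs(assigns)
        assert props["Family"] == pytest.approx(0.10)
        assert props["unlabeled"] == pytest.approx(0.90)

    def test_all_unlabeled(self):
        props = pool_runs([self._assignment(None) for _ in range(7)])
        assert props == {"unlabeled": 1.0}

    def test_proportions_sum_to_one(self):
        assigns = [self._assignment(lab) for lab in
                   ["Family", "Family", None, "Mental health", None]]
        assert sum(pool_runs(assigns).values()) == pytest.approx(1.0)

    def test_invariant_to_run_order(self):
        assigns = [self._assignment("Family", run_id=r) for r in range(3)]
        assigns += [self._assignment(None, run_id=r) for r in range(3)]
        assert pool_runs(assigns) == pool_runs(list(reversed(assigns)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_runs([])

    def test_category_mismatch_rejected(self):
        with pytest.raises(ValueError, match="other categories"):
            pool_runs([self._assignment("Family", category="A")], category="B")
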