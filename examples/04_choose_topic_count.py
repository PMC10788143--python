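"""Choose the number of topics with coherence + similarity ranks.

Scans candidate topic counts on a corpus planted with 5 disjoint-support
topics. For each K the mean topic coherence C (sliding-window NPMI /
cosine) and mean pairwise Jaccard similarity S are computed; the K with
the best combined rank (i-th highest C plus j-th smallest S, minimal
i + j) is selected.
"""

from sdohtopics import GeneratorConfig, build_matrix, generate_corpus, scan_k, tokenize
from sdohtopics.labeling import LabelDictionary
from sdohtopics.synthetic import background_vocabulary

words = background_vocabulary(300)
planted = LabelDictionary(
    {f"planted{k}": frozenset(words[k * 20 : (k + 1) * 20]) for k in range(5)},
    provenance="synthetic",
)
config = GeneratorConfig(seed=0, plant_sdoh=True, vocabulary=tuple(sorted(words)),
                         n_docs_per_category=150, doc_length_mean=100.0,
                         category_topic_boost={}, short_note_rate=0,
                         duplicate_rate=0, nonsocial_rate=0)
notes, _ = generate_corpus(config, dictionary=planted)
tokens = [tokenize(n.text) for n in notes]
dtm, _ = build_matrix(tokens)

ranked, selected, _ = scan_k(dtm, tokens, k_grid=range(3, 10), seeds=[11],
                             max_iter=40)
print("K    C       S       i  j  i+j")
for r in ranked:
    mark = "  <- selected" if r.K == selected else ""
    print(f"{r.K:<4d}{r.C:<8.4f}{r.S:<8.4f}{r.i:<3d}{r.j:<3d}{r.i + r.j}{mark}")
print(f"\nselected K = {selected} (planted truth: 5)")
# High C means a topic's top words co-occur tightly; low S means topics
# do not repeat each other. The combined rank balances the two.
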