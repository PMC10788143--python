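"""Fit LDA by variational Bayes and read off the topics.

Generates a planted corpus, filters and vectorizes it, fits an
11-topic model, and prints each topic's top words. With well-separated
planted topics the fitted top words reproduce the planted keyword sets.
"""

from sdohtopics import (
    GeneratorConfig,
    build_matrix,
    filter_notes,
    fit_lda,
    generate_corpus,
    load_stopwords,
    select_social_notes,
    top_words,
    tokenize,
)

notes, truth = generate_corpus(GeneratorConfig(seed=1, n_docs_per_category=100))
kept, _ = filter_notes(select_social_notes(notes))
stop = load_stopwords()
dtm, _ = build_matrix([tokenize(n.text, stop) for n in kept])

model = fit_lda(dtm, K=11, seed=3)
print(f"fit {model.K} topics on {dtm.n_docs} docs in {model.n_iterations} "
      f"iterations (converged={model.converged})")
print(f"final ELBO {model.elbo:.1f}; ELBO is non-decreasing across iterations")
for t in range(model.K):
    print(f"  topic {t:2d}: {' '.join(top_words(model, t, 6))}")
# Each line is one inferred topic's highest-probability words; compare
# them with the planted keyword sets in truth.topic_names / truth.phi.
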