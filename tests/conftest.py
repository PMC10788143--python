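import json
from importlib import resources

import pytest

from sdohtopics import preprocessing
from sdohtopics.corpus import DocTermMatrix
from sdohtopics.labeling import LabelDictionary, load_label_dictionary
from sdohtopics.synthetic import GeneratorConfig, background_vocabulary, generate_corpus


@pytest.fixture(scope="session")
def stopwords():
    return preprocessing.load_stopwords()


@pytest.fixture(scope="session")
def dictionary():
    return load_label_dictionary()


@pytest.fixture(scope="session")
def reference_topics():
    """Packaged full-corpus topic clusters (17 topics, top-10 words)."""
    text = (
        resources.files("sdohtopics")
        .joinpath("data/reference_topics.json")
        .read_text("utf-8")
    )
    return {int(k): tuple(v) for k, v in json.loads(text)["topics"].items()}


@pytest.fixture(scope="session")
def disjoint_dictionary():
    """Five labels with disjoint 20-word supports, for recovery tests."""
    words = background_vocabulary(300)
    labels = {f"planted{k}": frozenset(words[k * 20 : (k + 1) * 20]) for k in range(5)}
    return LabelDictionary(labels, provenance="synthetic"), tuple(sorted(words))


def disjoint_corpus(seed, dictionary, vocabulary, n_docs_per_type=250,
                    doc_length_mean=100.0):
    """A planted corpus with k_true=5 disjoint supports and no contaminants."""
    cfg = GeneratorConfig(
        seed=seed,
        plant_sdoh=True,
        vocabulary=vocabulary,
        n_docs_per_category=n_docs_per_type,
        doc_length_mean=doc_length_mean,
        keyword_mass=0.9,
        alpha_true=0.1,
        category_topic_boost={},
        short_note_rate=0.0,
        duplicate_rate=0.0,
        nonsocial_rate=0.0,
    )
    return generate_corpus(cfg, dictionary=dictionary)


def vectorize(notes, stopwords=frozenset()):
    tokens = [preprocessing.tokenize(n.text, stopwords) for n in notes]
    dtm, vocab = preprocessing.build_matrix(tokens)
    return dtm, tokens


@pytest.fixture(scope="session")
def small_planted_fit():
    """A modest planted corpus plus one fitted model, shared across tests."""
    from sdohtopics.lda import fit_lda

    cfg = GeneratorConfig(seed=1, n_docs_per_category=100)
    notes, truth = generate_corpus(cfg)
    from sdohtopics.preprocessing import filter_notes, select_social_notes

    kept, _ = filter_notes(select_social_notes(notes))
    dtm, tokens = vectorize(kept)
    model = fit_lda(dtm, 11, seed=3, max_iter=60)
    return dtm, tokens, model, truth


def subset_dtm(dtm: DocTermMatrix, rows) -> DocTermMatrix:
    rows = list(rows)
    return DocTermMatrix(dtm.counts[rows], dtm.vocabulary,
                         tuple(dtm.note_ids[i] for i in rows))
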