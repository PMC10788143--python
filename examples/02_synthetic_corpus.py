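"""Generate a synthetic social-work-note corpus with planted topics.

Each document is drawn from the LDA generative process with one planted
topic per label of the packaged SDoH keyword dictionary; metadata spans
4 note types and 10 disease chapters, and contaminants (short notes,
duplicates, non-social metadata) are injected at known rates.
"""

from collections import Counter

from sdohtopics import GeneratorConfig, generate_corpus

config = GeneratorConfig(seed=0, n_docs_per_category=50)
notes, truth = generate_corpus(config)

print(f"{len(notes)} notes from {truth.phi.shape[0]} planted topics "
      f"over {len(truth.vocabulary)} words")
print(f"contaminants: {truth.n_short} short, {truth.n_duplicates} duplicate, "
      f"{truth.n_nonsocial} non-social")
print("note types:", dict(Counter(n.note_type for n in notes)))
print("example planted topic "
      f"({truth.topic_names[0]}): {' '.join(truth.topic_support(0, 8))}")
print("example note:", notes[0].text[:70], "...")
# truth.theta holds each clean document's true topic mixture, so
# downstream inference can be scored against what was actually planted.
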