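"""Select social work notes, apply quality filters, build the count matrix.

Builds a handful of in-memory notes, keeps the ones whose routing
metadata mentions "social", drops a too-short note and an exact
duplicate, then tokenizes and counts what survives.
"""

from sdohtopics import (
    Note,
    build_matrix,
    filter_notes,
    load_stopwords,
    select_social_notes,
    tokenize,
)

notes = [
    Note("n1", "p1", "Patient reports stable housing and family support.",
         provider_type="Clinical Social Worker"),
    Note("n2", "p1", "Patient reports stable housing and family support.",
         provider_type="Clinical Social Worker"),  # exact duplicate of n1
    Note("n3", "p2", "ok",  # under 30 characters
         department_name="Social Work"),
    Note("n4", "p3", "Cardiology follow-up, ejection fraction stable.",
         department_name="Cardiology", provider_type="MD"),  # not social work
    Note("n5", "p2", "Discussed insurance coverage and transportation barriers.",
         specialty="Psychosocial Services"),
]

social = select_social_notes(notes)
kept, counts = filter_notes(social)
print(f"{len(notes)} notes in; {len(notes) - len(social)} without 'social' metadata")
print(f"dropped {counts.n_short} short and {counts.n_duplicate} duplicate notes; "
      f"{counts.n_kept} kept")

stop = load_stopwords()
tokens = [tokenize(n.text, stop) for n in kept]
dtm, vocab = build_matrix(tokens)
print(f"document-term matrix: {dtm.n_docs} docs x {dtm.n_words} words, "
      f"{dtm.total_tokens()} tokens")
print("vocabulary:", " ".join(vocab.words))
# Each row of the matrix counts one note's tokens after lowercasing,
# punctuation/digit stripping and stop-word removal.
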