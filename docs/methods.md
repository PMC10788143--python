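# Methods

## Model

`sdohtopics` treats a corpus of clinical social work notes as a bag-of-words
collection generated by latent Dirichlet allocation: document d draws a
topic mixture θ_d ~ Dirichlet(α), topic k draws a word distribution
β_k ~ Dirichlet(η), and each token draws a topic z ~ θ_d and then a word
w ~ β_z. Topics are interpreted through their highest-probability words
and, downstream, through a curated keyword dictionary of
social-determinants themes.

## Preprocessing

Social work notes are identified by a case-insensitive substring match of
"social" in any of four routing fields (encounter type, department name,
specialty, provider type); missing fields count as empty. Quality
filtering then drops notes whose raw text is under 30 characters (strict
`< 30`, measured in characters on the raw string) and exact duplicate
texts (string equality after normalizing line endings, first occurrence
kept). Length filtering runs before deduplication so a short duplicate is
counted as short, and both counts are reported for audit. Filtering is
idempotent, and it commutes with social selection except in the corner
case where the same text occurs in both a social and a non-social note —
the pipeline therefore always selects first, mirroring how such corpora
are retrieved.

Tokens are maximal runs of ASCII letters after lowercasing; digits,
punctuation and all whitespace (tabs, newlines, spaces) act as
separators. Stop words come from a packaged static copy of the standard
English list so results cannot drift with library versions. No
document-frequency pruning is applied to the vocabulary, which is sorted
lexicographically to make vectorization deterministic.

## Variational inference

The engine runs batch mean-field coordinate ascent with the standard
digamma updates: per-document Dirichlet parameters γ (E step, inner loop
capped at 60 sweeps or a mean-change below 1e-3 per topic) and the global
topic-word pseudo-count matrix λ (M step). Batch updates — rather than
online/minibatch variants that share the same fixed points — make every
fit exactly reproducible and let the tests assert that the evidence lower
bound never decreases (slack 1e-8 relative). Convergence is declared when
the relative ELBO change drops below 1e-4, with a 200-iteration cap
(pipeline runs use lower caps, see below).

Defaults and choices:

- **Priors**: symmetric α = η = 1/K, the common library default; the
  analysis that motivated this package reported none.
- **Initialization**: λ is seeded from Gamma(100, 0.01) draws, the
  standard pseudo-count initialization for this family of estimators. A
  Dirichlet(η) draw with η = 1/K is close to a vertex of the simplex and
  stalls the updates, so it is not used.
- **Top words**: ranked by descending topic-word probability with
  lexicographic tie-breaks, 10 per topic by convention.
- **Degenerate cases**: K = 1 yields θ ≡ 1 and a single topic equal to
  the η-smoothed corpus word distribution; K larger than the document
  count is allowed with a warning; an empty corpus is an error.

Variational inference on LDA is multimodal: independent restarts can land
in different local optima. The pipeline runs 5 independently seeded
replicates per analysis and pools their labeled clusters, which is also
how the cross-check against scikit-learn's batch implementation is
performed in the tests (best of a few restarts, held-out perplexity
within 10%).

## Choosing the number of topics

Coherence C of a topic's top words uses boolean sliding windows: a window
of 110 tokens (the convention for this coherence variant; configurable)
slides over each document, a document shorter than the window
contributing a single window. Word and pair probabilities are estimated
as window fractions. Each top word gets a vector of NPMI values against
the full top-word set (one-set segmentation; the self-pair has NPMI 1, a
never-co-occurring pair −1, and an absent word receives probability 1e-12
with a warning), and the topic scores the mean cosine between each word's
vector and the summed vector. A single top word scores 1 by convention.

Topic similarity S is the mean pairwise Jaccard similarity of the
top-word sets. For a grid of candidate K (default 10–50), C and S are
averaged over replicate fits per K before ranking; rank i orders C
descending, rank j orders S ascending, both with competition ranking
(ties share the better rank), and the K minimizing i + j is selected with
ties broken toward the smaller K. Ranking happens within one scan — not
across replicate runs — which is the stated interpretation of the
combined-rank rule.

## Topic labeling

The packaged dictionary maps 11 SDoH labels to lowercase keyword sets
(9–17 words each). A topic cluster — its top-10 word set — is compared
with every label by intersection-over-union; the set form is used
throughout (the operational definition in the labeling pseudocode), with
IOU comparisons done by exact integer cross-multiplication so the argmax
and its lexicographic tie-break are fully deterministic. The winning
label is assigned only when the overlap is at least 2 words; otherwise
the cluster stays in an explicit "unlabeled" bucket. Pooling over
replicate runs divides each label's cluster count by the total cluster
count, so proportions sum to 1 and are invariant to run order.

An optional expansion step grows keyword sets with embedding nearest
neighbors (cosine similarity, n per keyword). The manual relevance review
used when such dictionaries are built by hand is replaced by explicit
allow/deny lists, keeping expansion reproducible. The packaged dictionary
contains exactly the curated keywords, without expansion terms.

## Stratification and word frequencies

Ten ICD-10 disease-chapter ranges (nervous G00–G99, circulatory I00–I99,
respiratory J00–J99, digestive K00–K95, musculoskeletal M00–M99,
genitourinary N00–N99, pregnancy O00–O9A, congenital Q00–Q99, neoplasms
C00–D49, blood D50–D89) are matched on a code's first three characters
after uppercasing; codes outside all ranges, and malformed codes (no
leading letter, fewer than three characters) map to no chapter, the
latter with a warning. A note with codes in several chapters contributes
to each matching stratum; notes with no mappable code stay in note-type
strata only.

Label proportions per stratum are cluster-count shares from the pooled
assignments (the primary output; document-topic mass aggregation would be
an alternative reading). Word-frequency comparison uses the one-vs-rest
chi-squared statistic on word counts per category — the feature-selection
convention, one binary test per category, which yields a per-category
ranking — with words ranked by ascending p-value, stop words removed, the
top 5 reported, and a heatmap matrix of per-stratum frequency proportions
(word count / stratum token count).

## Synthetic corpora

The generator emulates the structure of a social-work-note corpus at desk
scale: 4 note types with a strongly skewed size distribution (Progress ≫
Interdisciplinary ≫ Telephone ≫ Group, default 400/200/100/50 clean
documents), one representative ICD-10 code per chapter (G35, I10, J45,
K21, M54, N18, O80, Q21, C50, D64) with a 10% chance of a second-chapter
code, and "social" routing metadata. Planted mode creates one topic per
dictionary label with 90% of its mass uniform on the label's keywords and
the rest uniform on a background vocabulary of 500 deterministic
four-letter filler words. Per-note-type Dirichlet boosts (Group session
×6 in Group Notes, telephone ×4 in Telephone encounters,
clinician/medication ×2 in Progress Notes) mirror the thematic skew real
note types show. Document lengths are Poisson (mean 60, floor 10 tokens
so no clean document trips the 30-character filter); topic mixtures use
α = 0.1 (a few topics per note). Contaminants — notes under 30
characters, exact duplicates of clean notes, notes without "social"
metadata — are injected at 2% each by default, with identities recorded
in the ground truth.

What the generator does **not** emulate: grammar, negation, note
sections, spelling variation, vocabulary burstiness, or any
protected-content realism. Passing tests therefore demonstrate that the
algorithms are implemented correctly and recover planted structure under
the stated noise; they do not certify performance on real clinical text.

## Problem sizes and test conditions

Desk-scale runs use corpora of a few thousand documents. The cluster
bookkeeping analysis uses 500 clean documents per note type (≈ 200 per
chapter stratum after code assignment), K = 20, 5 replicate runs across
the 14 strata — 1400 pooled clusters. Planted-recovery experiments use 5
topics on disjoint 20-word supports, 1000 documents of mean length 100,
with recovery demanded for ≥ 4 of 5 supports at ≥ 8/10 top-word agreement
in ≥ 4 of 5 seeds; the K scan for these corpora covers 3–9 (a grid that
brackets the planted truth, unlike the 10–50 production default) and must
land within ±2 of the truth in ≥ 3 of 5 repetitions. Pipeline fits cap
iterations at 25–60; at these corpus sizes the ELBO criterion typically
triggers after roughly 10 sweeps.

## Known limitations

- Batch inference scales as documents × topics × vocabulary per sweep;
  corpora in the hundreds of thousands of documents would need the online
  variant this package deliberately avoids for determinism.
- Coherence window counting enumerates window sets naively, which is fine
  for documents near or below the window size but quadratic in distinct
  window words for very long documents.
- The labeling heuristic sees only top-word sets; two topics with
  identical supports but different weight profiles label identically.
- Stop-word removal and alphabetic-only tokens discard numerals and
  clinical shorthand (e.g. "10/10 pain"), a deliberate simplification.
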