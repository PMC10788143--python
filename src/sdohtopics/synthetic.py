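"""Synthetic social-work-note corpora with planted topic structure.

Documents are drawn from the LDA generative process: a per-document
topic mixture theta ~ Dirichlet(alpha), then for every token a topic
z ~ theta and a word w ~ phi_z. In planted mode one topic per label of
the packaged keyword dictionary is created, concentrating most of its
probability mass on that label's keyword set, so the full pipeline
(filtering, inference, model selection, labeling, stratification) can
be exercised end to end with a known ground truth.

Metadata emulates the corpus the pipeline targets: four note-type
categories with a strongly skewed size distribution, one or two
encounter ICD-10 codes per note spanning ten disease chapters, and
"social" routing metadata. Contaminants — notes under 30 characters,
exact duplicates, and notes without "social" metadata — are injected at
configurable rates to exercise the selection and quality filters.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import Note
from .labeling import LabelDictionary, load_label_dictionary

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_corpus",
    "plant_sdoh_topics",
    "background_vocabulary",
    "NOTE_TYPES",
    "CHAPTER_CODES",
]

NOTE_TYPES = ("Progress Notes", "Interdisciplinary", "Telephone encounters", "Group Notes")

# One representative 3-character code per disease chapter stratum.
CHAPTER_CODES = ("G35", "I10", "J45", "K21", "M54", "N18", "O80", "Q21", "C50", "D64")

_SOCIAL_META = dict(
    encounter_type="Office Visit",
    department_name="Social Work",
    specialty="Psychosocial Services",
    provider_type="Clinical Social Worker",
)
_NONSOCIAL_META = dict(
    encounter_type="Office Visit",
    department_name="Cardiology",
    specialty="Internal Medicine",
    provider_type="MD",
)


def background_vocabulary(
    n_words: int, exclude: frozenset[str] = frozenset()
) -> list[str]:
    """Deterministic list of pronounceable 4-letter filler words."""
    cons = "bcdfglmnprstvz"
    vow = "aeiou"
    syllables = [c + v for c in cons for v in vow]
    words = []
    for s1 in syllables:
        for s2 in syllables:
            w = s1 + s2
            if w not in exclude:
                words.append(w)
            if len(words) == n_words:
                return words
    raise ValueError(f"cannot generate {n_words} background words")


@dataclass
class GeneratorConfig:
    """Conditions for one synthetic corpus draw.

    With ``plant_sdoh=True`` (the default) the planted topics are the 11
    labels of the packaged dictionary and ``k_true`` is ignored in favor
    of the label count. ``n_docs_per_category`` may be a single int
    (every note type gets that many clean documents) or a mapping from
    note type to count; the default skew mirrors a corpus dominated by
    progress notes. Contamination rates are fractions of the clean
    document count.
    """

    k_true: int = 11
    plant_sdoh: bool = True
    vocabulary: Sequence[str] | None = None
    n_background_words: int = 500
    keyword_mass: float = 0.9
    alpha_true: float = 0.1
    eta_true: float = 0.01
    n_docs_per_category: int | Mapping[str, int] | None = None
    note_types: Sequence[str] = NOTE_TYPES
    chapter_codes: Sequence[str] = CHAPTER_CODES
    doc_length_mean: float = 60.0
    min_doc_tokens: int = 10
    multi_chapter_rate: float = 0.1
    short_note_rate: float = 0.02
    duplicate_rate: float = 0.02
    nonsocial_rate: float = 0.02
    category_topic_boost: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "Group Notes": {"Group session": 6.0},
            "Telephone encounters": {"TelephoneEcounter/online communication": 4.0},
            "Progress Notes": {"Clinician/hospital/medication": 2.0},
        }
    )
    seed: int = 0

    def docs_per_category(self) -> dict[str, int]:
        if self.n_docs_per_category is None:
            skew = {
                "Progress Notes": 400,
                "Interdisciplinary": 200,
                "Telephone encounters": 100,
                "Group Notes": 50,
            }
            return {t: skew.get(t, 100) for t in self.note_types}
        if isinstance(self.n_docs_per_category, int):
            return {t: self.n_docs_per_category for t in self.note_types}
        return {t: int(self.n_docs_per_category[t]) for t in self.note_types}

    def validate(self) -> None:
        for r in (
            self.short_note_rate,
            self.duplicate_rate,
            self.nonsocial_rate,
            self.multi_chapter_rate,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.doc_length_mean <= 0:
            raise ValueError("doc_length_mean must be positive")
        if not 0.0 < self.keyword_mass <= 1.0:
            raise ValueError("keyword_mass must lie in (0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    phi: np.ndarray  # k_true x V topic-word simplex
    topic_names: tuple[str, ...]
    vocabulary: tuple[str, ...]
    theta: dict[str, np.ndarray]  # note_id -> mixture (clean docs only)
    note_type: dict[str, str]
    chapter_codes: dict[str, tuple[str, ...]]
    short_note_ids: tuple[str, ...]
    duplicate_note_ids: tuple[str, ...]
    nonsocial_note_ids: tuple[str, ...]

    @property
    def n_short(self) -> int:
        return len(self.short_note_ids)

    @property
    def n_duplicates(self) -> int:
        return len(self.duplicate_note_ids)

    @property
    def n_nonsocial(self) -> int:
        return len(self.nonsocial_note_ids)

    def topic_support(self, k: int, n: int = 20) -> list[str]:
        order = np.argsort(-self.phi[k])
        return [self.vocabulary[i] for i in order[:n]]


def plant_sdoh_topics(
    dictionary: LabelDictionary,
    vocabulary: Sequence[str],
    keyword_mass: float = 0.9,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """One planted topic per dictionary label.

    A fraction ``keyword_mass`` of each topic's probability is spread
    uniformly over that label's keywords; the remainder goes uniformly
    over the rest of the vocabulary. Every keyword must be present in
    the vocabulary.
    """
    vocab_index = {w: i for i, w in enumerate(vocabulary)}
    names = tuple(sorted(dictionary))
    V = len(vocabulary)
    phi = np.zeros((len(names), V))
    for k, name in enumerate(names):
        keys = dictionary[name]
        missing = sorted(w for w in keys if w not in vocab_index)
        if missing:
            raise ValueError(
                f"vocabulary is missing keywords of label {name!r}: {missing}"
            )
        idx = [vocab_index[w] for w in keys]
        rest_mass = 1.0 - keyword_mass
        if len(idx) == V:
            phi[k, idx] = 1.0 / V
            continue
        phi[k, :] = rest_mass / (V - len(idx))
        phi[k, idx] = keyword_mass / len(idx)
    return phi, names


def _random_topics(
    k_true: int, n_words: int, eta_true: float, rng: np.random.Generator
) -> tuple[np.ndarray, tuple[str, ...]]:
    phi = rng.dirichlet(np.full(n_words, eta_true), size=k_true)
    names = tuple(f"topic-{k}" for k in range(k_true))
    return phi, names


def generate_corpus(
    config: GeneratorConfig,
    dictionary: LabelDictionary | None = None,
) -> tuple[list[Note], GroundTruth]:
    """Draw a corpus (clean documents plus contaminants) and its truth.

    Identical configs (same seed) yield byte-identical corpora.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    if config.plant_sdoh:
        if dictionary is None:
            dictionary = load_label_dictionary()
        keywords = frozenset(w for keys in dictionary.labels.values() for w in keys)
        if config.vocabulary is not None:
            vocab = tuple(config.vocabulary)
            phi, names = plant_sdoh_topics(dictionary, vocab, config.keyword_mass)
        else:
            bg = background_vocabulary(config.n_background_words, exclude=keywords)
            vocab = tuple(sorted(keywords | set(bg)))
            phi, names = plant_sdoh_topics(dictionary, vocab, config.keyword_mass)
    else:
        if config.vocabulary is not None:
            vocab = tuple(config.vocabulary)
        else:
            vocab = tuple(background_vocabulary(config.n_background_words))
        phi, names = _random_topics(config.k_true, len(vocab), config.eta_true, rng)

    k_true = phi.shape[0]
    name_to_topic = {n: k for k, n in enumerate(names)}
    vocab_arr = np.asarray(vocab, dtype=object)

    per_cat = config.docs_per_category()
    total_clean = sum(per_cat.values())
    # skewed patient pool so notes-per-patient strata are populated
    n_patients = max(1, total_clean // 3)
    patient_weights = 1.0 / np.arange(1, n_patients + 1)
    patient_weights /= patient_weights.sum()

    notes: list[Note] = []
    theta_by_id: dict[str, np.ndarray] = {}
    type_by_id: dict[str, str] = {}
    chapters_by_id: dict[str, tuple[str, ...]] = {}

    doc_no = 0
    for note_type in config.note_types:
        alpha_vec = np.full(k_true, config.alpha_true)
        for label, factor in config.category_topic_boost.get(note_type, {}).items():
            if label in name_to_topic:
                alpha_vec[name_to_topic[label]] *= factor
        for _ in range(per_cat[note_type]):
            theta = rng.dirichlet(alpha_vec)
            length = max(config.min_doc_tokens, int(rng.poisson(config.doc_length_mean)))
            topic_counts = rng.multinomial(length, theta)
            tokens: list[str] = []
            for k in range(k_true):
                if topic_counts[k]:
                    word_counts = rng.multinomial(topic_counts[k], phi[k])
                    tokens.extend(np.repeat(vocab_arr, word_counts).tolist())
            rng.shuffle(tokens)

            codes = [str(rng.choice(np.asarray(config.chapter_codes)))]
            if rng.random() < config.multi_chapter_rate and len(config.chapter_codes) > 1:
                other = [c for c in config.chapter_codes if c != codes[0]]
                codes.append(str(rng.choice(np.asarray(other))))

            note_id = f"syn-{doc_no:06d}"
            doc_no += 1
            notes.append(
                Note(
                    note_id=note_id,
                    patient_id=f"pt-{rng.choice(n_patients, p=patient_weights):06d}",
                    text=" ".join(tokens),
                    note_type=note_type,
                    icd10_codes=tuple(codes),
                    year=int(rng.integers(2012, 2022)),
                    **_SOCIAL_META,
                )
            )
            theta_by_id[note_id] = theta
            type_by_id[note_id] = note_type
            chapters_by_id[note_id] = tuple(codes)

    # --- contaminants ---------------------------------------------------
    n_short = int(round(config.short_note_rate * total_clean))
    n_dup = int(round(config.duplicate_rate * total_clean))
    n_nonsocial = int(round(config.nonsocial_rate * total_clean))

    short_ids, dup_ids, nonsocial_ids = [], [], []
    letters = np.asarray(list(string.ascii_lowercase))
    for _ in range(n_short):
        note_id = f"syn-{doc_no:06d}"
        doc_no += 1
        n_chars = int(rng.integers(1, 30))
        text = "".join(rng.choice(letters, size=n_chars))
        notes.append(
            Note(
                note_id=note_id,
                patient_id=f"pt-{rng.choice(n_patients, p=patient_weights):06d}",
                text=text[:29],
                note_type=str(rng.choice(np.asarray(config.note_types))),
                icd10_codes=(str(rng.choice(np.asarray(config.chapter_codes))),),
                year=int(rng.integers(2012, 2022)),
                **_SOCIAL_META,
            )
        )
        short_ids.append(note_id)

    for _ in range(n_dup):
        src = notes[int(rng.integers(0, total_clean))]
        note_id = f"syn-{doc_no:06d}"
        doc_no += 1
        notes.append(
            Note(
                note_id=note_id,
                patient_id=src.patient_id,
                text=src.text,
                note_type=src.note_type,
                icd10_codes=src.icd10_codes,
                year=src.year,
                **_SOCIAL_META,
            )
        )
        dup_ids.append(note_id)

    for i in range(n_nonsocial):
        note_id = f"syn-{doc_no:06d}"
        doc_no += 1
        theta = rng.dirichlet(np.full(k_true, config.alpha_true))
        length = max(config.min_doc_tokens, int(rng.poisson(config.doc_length_mean)))
        topic_counts = rng.multinomial(length, theta)
        tokens = []
        for k in range(k_true):
            if topic_counts[k]:
                word_counts = rng.multinomial(topic_counts[k], phi[k])
                tokens.extend(np.repeat(vocab_arr, word_counts).tolist())
        rng.shuffle(tokens)
        notes.append(
            Note(
                note_id=note_id,
                patient_id=f"pt-{rng.choice(n_patients, p=patient_weights):06d}",
                text=" ".join(tokens) + f" marker{i}",  # keep texts unique
                note_type=str(rng.choice(np.asarray(config.note_types))),
                icd10_codes=(str(rng.choice(np.asarray(config.chapter_codes))),),
                year=int(rng.integers(2012, 2022)),
                **_NONSOCIAL_META,
            )
        )
        nonsocial_ids.append(note_id)

    truth = GroundTruth(
        phi=phi,
        topic_names=names,
        vocabulary=vocab,
        theta=theta_by_id,
        note_type=type_by_id,
        chapter_codes=chapters_by_id,
        short_note_ids=tuple(short_ids),
        duplicate_note_ids=tuple(dup_ids),
        nonsocial_note_ids=tuple(nonsocial_ids),
    )
    return notes, truth
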