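"""End-to-end orchestration: filter -> vectorize -> fit -> label -> stratify.

A run is driven by a single RunConfig and a master seed; every random
draw (synthetic corpus, replicate fits, K scans) flows from seeds
derived from it, and the derived seeds are recorded in the report, so
a rerun with the same config is byte-identical. Each stage writes its
artifacts as soon as they exist; a failure aborts with the stage name
while earlier artifacts stay on disk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import preprocessing, strata
from .corpus import Note, read_notes_jsonl, write_notes_jsonl
from .labeling import LabelAssignment, assign_label, load_label_dictionary
from .lda import TopicCluster, clusters_from_models, run_replicates
from .selection import scan_k
from .synthetic import GeneratorConfig, generate_corpus

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "summarize_cohort",
    "cohort_from_note_counts",
]

MODES = ("full-corpus", "per-note-type", "per-chapter", "synthetic")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    ``k_override`` skips the K scan; the defaults (17 for the full
    corpus, 20 for category strata) are the topic counts the scan
    settles on at corpus scale. ``k_grid`` is only consulted when
    ``k_override`` is None.
    """

    mode: str = "synthetic"
    input_path: str | None = None
    output_dir: str = "run_output"
    k_grid: tuple[int, ...] = tuple(range(10, 51))
    k_override: int | None = None
    n_runs: int = 5
    seed: int = 0
    n_top_words: int = 10
    min_stratum_docs: int = 10
    max_iter: int = 60
    generator: GeneratorConfig | None = None
    dictionary_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not self.k_grid:
            raise ValueError("k_grid must be nonempty")

    def effective_k(self) -> int | None:
        if self.k_override is not None:
            return self.k_override
        return None

    def default_k(self) -> int:
        return 17 if self.mode == "full-corpus" else 20


class PipelineError(RuntimeError):
    """A stage failed; earlier artifacts are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def summarize_cohort(notes: Sequence[Note]) -> dict[str, int]:
    """Patients stratified by notes per patient: 1, 2-5 (inclusive), >5."""
    counts: dict[str, int] = {}
    for n in notes:
        counts[n.patient_id] = counts.get(n.patient_id, 0) + 1
    return cohort_from_note_counts(counts)


def cohort_from_note_counts(notes_per_patient: Mapping[str, int]) -> dict[str, int]:
    """Cohort table from a patient -> note-count mapping."""
    one = sum(1 for v in notes_per_patient.values() if v == 1)
    two_five = sum(1 for v in notes_per_patient.values() if 2 <= v <= 5)
    more = sum(1 for v in notes_per_patient.values() if v > 5)
    return {
        "patients_with_1_note": one,
        "patients_with_2_to_5_notes": two_five,
        "patients_with_more_than_5_notes": more,
        "total_patients": one + two_five + more,
    }


def _derive_seeds(master: int, n: int, stream: int) -> list[int]:
    rng = np.random.default_rng([stream, master])
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _write_clusters_tsv(path: Path, clusters: Sequence[TopicCluster]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("run_id\tcategory\ttopic\trank\tword\tweight\n")
        for c in clusters:
            for rank, (w, wt) in enumerate(zip(c.words, c.weights), 1):
                fh.write(f"{c.run_id}\t{c.category}\t{c.topic}\t{rank}\t{w}\t{wt:.8g}\n")


def _write_assignments_tsv(path: Path, assigns: Sequence[LabelAssignment]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("category\trun_id\ttopic\tlabel\toverlap\tunion\tiou\n")
        for a in assigns:
            fh.write(
                f"{a.category}\t{a.run_id}\t{a.topic}\t{a.label or ''}\t"
                f"{a.overlap}\t{a.union}\t{a.iou:.8g}\n"
            )


def _strata_for_mode(
    notes: Sequence[Note], mode: str, min_docs: int
) -> dict[str, list[Note]]:
    out: dict[str, list[Note]] = {}
    if mode == "full-corpus":
        out["all"] = list(notes)
        return out
    if mode in ("per-note-type", "synthetic"):
        by_type: dict[str, list[Note]] = {}
        for n in notes:
            by_type.setdefault(n.note_type or "(untyped)", []).append(n)
        out.update(sorted(by_type.items()))
    if mode in ("per-chapter", "synthetic"):
        for ch, ch_notes in strata.notes_by_chapter(notes).items():
            out[ch] = ch_notes
    return {k: v for k, v in out.items() if len(v) >= min_docs}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _config_dict(config), "stages": []}

    # --- stage: load / simulate ----------------------------------------
    stage = "load"
    try:
        if config.mode == "synthetic":
            gen = config.generator or GeneratorConfig(seed=config.seed)
            notes, truth = generate_corpus(gen)
            write_notes_jsonl(notes, outdir / "notes.jsonl")
            report["synthetic_truth"] = {
                "k_true": int(truth.phi.shape[0]),
                "topic_names": list(truth.topic_names),
                "n_short_injected": truth.n_short,
                "n_duplicates_injected": truth.n_duplicates,
                "n_nonsocial_injected": truth.n_nonsocial,
            }
        else:
            if config.input_path is None:
                raise ValueError(f"mode {config.mode!r} requires input_path")
            notes = read_notes_jsonl(config.input_path)
        report["n_notes_input"] = len(notes)
        report["stages"].append(stage)
    except Exception as e:  # noqa: BLE001 - abort with stage context
        raise PipelineError(stage, e) from e

    # --- stage: filter ---------------------------------------------------
    stage = "filter"
    try:
        social = preprocessing.select_social_notes(notes)
        kept, counts = preprocessing.filter_notes(social)
        if not kept:
            raise ValueError("no notes survive preprocessing")
        write_notes_jsonl(kept, outdir / "filtered.jsonl")
        report["filter"] = {
            "n_input": counts.n_input,
            "n_nonsocial_dropped": len(notes) - len(social),
            "n_short_dropped": counts.n_short,
            "n_duplicates_dropped": counts.n_duplicate,
            "n_kept": counts.n_kept,
        }
        report["cohort"] = summarize_cohort(kept)
        report["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --- stage: vectorize ------------------------------------------------
    stage = "vectorize"
    try:
        stopwords = preprocessing.load_stopwords()
        categories = _strata_for_mode(kept, config.mode, config.min_stratum_docs)
        if not categories:
            raise ValueError("no stratum has enough documents")
        tokens_by_cat = {
            cat: preprocessing.tokenize_notes(ns, stopwords)
            for cat, ns in categories.items()
        }
        dtm_by_cat = {}
        for cat, toks in tokens_by_cat.items():
            dtm, _ = preprocessing.build_matrix(toks)
            dtm_by_cat[cat] = dtm
        first = next(iter(dtm_by_cat))
        dtm_by_cat[first].save(outdir / "dtm.mtx", outdir / "vocabulary.txt")
        report["strata"] = {cat: len(ns) for cat, ns in categories.items()}
        report["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --- stage: choose K ---------------------------------------------------
    stage = "scan-k"
    try:
        k_by_cat: dict[str, int] = {}
        if config.k_override is not None:
            for cat in categories:
                k_by_cat[cat] = config.k_override
            report["k_selection"] = {"method": "override", "K": config.k_override}
        elif config.mode == "full-corpus" or len(config.k_grid) == 1:
            k = config.k_grid[0] if len(config.k_grid) == 1 else None
            if k is None:
                scan_seeds = _derive_seeds(config.seed, config.n_runs, stream=1)
                cat = next(iter(categories))
                ranked, k, _ = scan_k(
                    dtm_by_cat[cat],
                    tokens_by_cat[cat],
                    config.k_grid,
                    scan_seeds,
                    n_top=config.n_top_words,
                    max_iter=config.max_iter,
                )
                with open(outdir / "kscan.tsv", "w", encoding="utf-8") as fh:
                    fh.write("K\tC\tS\ti\tj\ti_plus_j\tselected\n")
                    for r in ranked:
                        fh.write(
                            f"{r.K}\t{r.C:.6f}\t{r.S:.6f}\t{r.i}\t{r.j}\t"
                            f"{r.i + r.j}\t{int(r.K == k)}\n"
                        )
            for cat in categories:
                k_by_cat[cat] = k
            report["k_selection"] = {"method": "scan", "K": k}
        else:
            for cat in categories:
                k_by_cat[cat] = config.default_k()
            report["k_selection"] = {"method": "default", "K": config.default_k()}
        report["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --- stage: fit replicates --------------------------------------------
    stage = "fit"
    try:
        seeds = _derive_seeds(config.seed, config.n_runs, stream=2)
        clusters: list[TopicCluster] = []
        for cat in categories:
            models = run_replicates(
                dtm_by_cat[cat], k_by_cat[cat], seeds, max_iter=config.max_iter
            )
            clusters.extend(
                clusters_from_models(models, category=cat, n_words=config.n_top_words)
            )
        _write_clusters_tsv(outdir / "clusters.tsv", clusters)
        report["replicate_seeds"] = seeds
        report["n_topic_clusters"] = len(clusters)
        report["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --- stage: label ------------------------------------------------------
    stage = "label"
    try:
        dictionary = load_label_dictionary(config.dictionary_path)
        assignments = [
            assign_label(c.words, dictionary, run_id=c.run_id,
                         category=c.category, topic=c.topic)
            for c in clusters
        ]
        _write_assignments_tsv(outdir / "assignments.tsv", assignments)
        by_cat: dict[str, list[LabelAssignment]] = {}
        for a in assignments:
            by_cat.setdefault(a.category, []).append(a)
        proportions = strata.topic_proportions(by_cat, labels=sorted(dictionary))
        proportions.to_csv(outdir / "proportions.tsv", sep="\t")
        report["label_proportions"] = {
            cat: {lab: round(v, 6) for lab, v in row.items() if v > 0}
            for cat, row in proportions.iterrows()
        }
        report["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --- stage: word frequency ---------------------------------------------
    stage = "word-frequency"
    try:
        if config.mode != "full-corpus":
            chi2_report = {}
            for scheme in ("note_type", "chapter"):
                labels = _doc_categories(kept, scheme)
                usable = [i for i, lab in enumerate(labels) if lab is not None]
                cats_present = {labels[i] for i in usable}
                if len(cats_present) < 2 or len(usable) < 2:
                    continue
                sub_notes = [kept[i] for i in usable]
                sub_tokens = preprocessing.tokenize_notes(sub_notes, stopwords)
                sub_dtm, _ = preprocessing.build_matrix(sub_tokens)
                sub_labels = [labels[i] for i in usable]
                top = strata.chi2_word_selection(sub_dtm, sub_labels, stopwords)
                words = sorted({w for lst in top.values() for w, _, _ in lst})
                heat = strata.word_frequency_heatmap(sub_dtm, sub_labels, words)
                heat.to_csv(outdir / f"word_frequency_{scheme}.tsv", sep="\t")
                chi2_report[scheme] = {
                    cat: [w for w, _, _ in lst] for cat, lst in top.items()
                }
            report["chi2_top_words"] = chi2_report
        report["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --- stage: report -------------------------------------------------------
    report_json = json.dumps(report, indent=2, sort_keys=True)
    (outdir / "report.json").write_text(report_json + "\n", encoding="utf-8")
    (outdir / "report.txt").write_text(_human_report(report), encoding="utf-8")
    return report


def _doc_categories(notes: Sequence[Note], scheme: str) -> list[str | None]:
    if scheme == "note_type":
        return [n.note_type or None for n in notes]
    out: list[str | None] = []
    for n in notes:
        ch = None
        for code in n.icd10_codes:
            ch = strata.map_icd10_chapter(code)
            if ch is not None:
                break
        out.append(ch)
    return out


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("generator") is not None:
        gen = d["generator"]
        for key, val in list(gen.items()):
            if isinstance(val, tuple):
                gen[key] = list(val)
    d["k_grid"] = list(d["k_grid"])
    return d


def _human_report(report: dict) -> str:
    lines = ["pipeline run report", "===================", ""]
    lines.append(f"input notes: {report.get('n_notes_input')}")
    f = report.get("filter", {})
    lines.append(
        "filtering: "
        f"{f.get('n_nonsocial_dropped', 0)} non-social, "
        f"{f.get('n_short_dropped', 0)} short, "
        f"{f.get('n_duplicates_dropped', 0)} duplicates dropped; "
        f"{f.get('n_kept', 0)} kept"
    )
    c = report.get("cohort", {})
    lines.append(
        f"cohort: {c.get('total_patients', 0)} patients "
        f"({c.get('patients_with_1_note', 0)} with 1 note, "
        f"{c.get('patients_with_2_to_5_notes', 0)} with 2-5, "
        f"{c.get('patients_with_more_than_5_notes', 0)} with >5)"
    )
    ks = report.get("k_selection", {})
    lines.append(f"topic count K: {ks.get('K')} ({ks.get('method')})")
    lines.append(f"topic clusters submitted to labeling: {report.get('n_topic_clusters')}")
    lines.append("")
    for cat, props in sorted(report.get("label_proportions", {}).items()):
        tops = sorted(props.items(), key=lambda kv: -kv[1])[:3]
        shown = ", ".join(f"{lab} {100 * v:.1f}%" for lab, v in tops)
        lines.append(f"  {cat}: {shown}")
    return "\n".join(lines) + "\n"
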