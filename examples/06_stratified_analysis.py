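"""Stratify a corpus by note type / disease chapter and compare strata.

Runs the full pipeline on a synthetic corpus (4 note types + 10 ICD-10
chapters = 14 strata, 5 replicate fits each), pools the labeled
clusters into per-stratum label proportions, and runs the one-vs-rest
chi-squared word comparison across note types.
"""

import tempfile

from sdohtopics import RunConfig, map_icd10_chapter, run_pipeline
from sdohtopics.synthetic import GeneratorConfig

print("chapter of G35:", map_icd10_chapter("G35"))
print("chapter of C50.9:", map_icd10_chapter("C50.9"))
print("chapter of Z99:", map_icd10_chapter("Z99"), "(outside the 10 ranges)\n")

with tempfile.TemporaryDirectory() as td:
    config = RunConfig(
        mode="synthetic", output_dir=td, k_override=11, n_runs=5, seed=2,
        generator=GeneratorConfig(seed=2, n_docs_per_category=150),
    )
    report = run_pipeline(config)

print(f"strata analyzed: {len(report['strata'])}")
print(f"topic clusters pooled: {report['n_topic_clusters']}")
for cat in ("Group Notes", "Telephone encounters", "Progress Notes"):
    props = report["label_proportions"][cat]
    top3 = sorted(props.items(), key=lambda kv: -kv[1])[:3]
    print(f"  {cat}: " + ", ".join(f"{lab} {100 * v:.1f}%" for lab, v in top3))
print("\nchi-squared top words by note type:")
for cat, words in report["chi2_top_words"]["note_type"].items():
    print(f"  {cat}: {' '.join(words)}")
# The generator boosts Group session topics in Group Notes and
# telephone topics in Telephone encounters; the pooled proportions and
# the discriminative words recover exactly those planted contrasts.
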