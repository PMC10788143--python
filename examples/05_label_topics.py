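"""Automatically label topic clusters with the SDoH keyword dictionary.

Labels the packaged reference topics (inferred once on a full
social-work-note corpus) by intersection-over-union against the 11-label
keyword dictionary: the max-IOU label wins if at least 2 words overlap,
otherwise the cluster stays unlabeled.
"""

import json
from importlib import resources

from sdohtopics import assign_label, load_label_dictionary, pool_runs

dictionary = load_label_dictionary()
print(f"dictionary: {len(dictionary)} labels, e.g. 'Mental health' -> "
      f"{' '.join(sorted(dictionary['Mental health'])[:5])} ...")

topics = json.loads(
    resources.files("sdohtopics").joinpath("data/reference_topics.json")
    .read_text("utf-8")
)["topics"]

assignments = []
for idx, words in topics.items():
    a = assign_label(words, dictionary, topic=int(idx))
    assignments.append(a)
    print(f"topic {idx:>2}: {a.label or '(unlabeled)':<40} "
          f"overlap={a.overlap} iou={a.iou:.3f}")

props = pool_runs(assignments)
print("\nlabel proportions over the 17 clusters:")
for label, p in sorted(props.items(), key=lambda kv: -kv[1]):
    print(f"  {label:<42} {100 * p:5.1f}%")
# A topic is only labeled when it shares >= 2 words with some label's
# keywords; the proportions show how much of the corpus-level topic
# space is explicitly SDoH-related.
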