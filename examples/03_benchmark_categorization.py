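"""Evaluate generated mappings against a human-verified benchmark.

Maps benchmark input phrases to the bundled disease ontology, then
categorizes each top-ranked mapping T against the benchmark term H using
the class hierarchy: Same (T = H), MoreSpecific (T subclass of H),
MoreGeneral (T superclass of H), Sibling (shared direct parent) or
Unrelated.  A high Same rate means the tool refinds the curated mappings;
the other categories tell you *how* the remaining mappings deviate.
"""

import tempfile
from pathlib import Path

from ontoground import BenchmarkEntry, compare_mapping_sets, load_ontology, map_terms
from ontoground.fixtures import table2_mirror_ontology

doc, expected = table2_mirror_ontology()
owl = Path(tempfile.mkdtemp()) / "diseases.owl"
owl.write_text(doc)
index = load_ontology(str(owl))

inputs = [text for text, _, _, _ in expected] + ["thyroiditis"]
benchmark = [BenchmarkEntry(text, h) for text, _, h, _ in expected]
benchmark.append(BenchmarkEntry("thyroiditis", "EFO:1000627"))  # CURIEs resolve too

table = map_terms(inputs, index)
report = compare_mapping_sets(table, benchmark, index)

print(f"{'Category':<14}{'Count':>6}{'Percent':>9}")
for name, count, pct in report.summary_rows():
    print(f"{name:<14}{count:>6}{pct:>8.1f}%")
print(
    f"\ncategorized={report.n_categorized}  unmapped_by_tool={report.unmapped_by_tool}  "
    f"deprecated_benchmark_terms={report.deprecated_benchmark}"
)
for text, t, h, cat in report.pairs:
    print(f"  {text!r:38} {cat.value:13} T={index.terms[t].identifier} H={index.terms[h].identifier}")
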