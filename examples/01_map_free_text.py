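"""Map free-text disease descriptions to a small OWL ontology.

Builds the bundled hand-written disease ontology, maps a few phrases with
the TF-IDF n-gram mapper, and prints the top candidates.  A score of 1.0
means the query equals one of the term's names after normalization — note
the synonym-aware hit for "heart attack", whose matching term is labeled
"myocardial infarction".
"""

import tempfile
from pathlib import Path

from ontoground import MapperConfig, load_ontology, map_terms
from ontoground.fixtures import table2_mirror_ontology

doc, _ = table2_mirror_ontology()
owl = Path(tempfile.mkdtemp()) / "diseases.owl"
owl.write_text(doc)
index = load_ontology(str(owl))
print(f"loaded {len(index)} terms from {owl.name}\n")

queries = ["heart attack", "Hayfever or allergic rhinitis", "cronic bronchitis", "zzqx"]
table = map_terms(queries, index, MapperConfig(max_mappings=2))

for row in table.rows:
    print(f"{row.source.text!r:38} -> {row.term_label:28} {row.term_curie:14} {row.score:.4f}")
for st in table.unmapped:
    print(f"{st.text!r:38} -> (unmapped: no candidate above the score threshold)")
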