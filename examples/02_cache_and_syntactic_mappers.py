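"""Generate a seeded toy ontology, cache it, and compare mapper families.

The processed index is stored on disk so repeated mapping jobs skip OWL
parsing.  The same typo'd query is then mapped with TF-IDF and with each
pairwise string metric; scores are normalized similarities in [0, 1], so
the ranking — not the absolute value — is what is comparable across
metrics.
"""

import tempfile
from pathlib import Path

from ontoground import MapperConfig, load_ontology, map_terms
from ontoground.fixtures import FixtureSpec, corrupt_label, generate_toy_ontology
from ontoground.metrics import SYNTACTIC_METRICS
from ontoground.ontology import load_cache, save_cache

work = Path(tempfile.mkdtemp())
doc, truth = generate_toy_ontology(FixtureSpec(n_terms=50, synonym_rate=0.5, seed=11))
owl = work / "toy.owl"
owl.write_text(doc)

index = load_ontology(str(owl))
save_cache(index, work / "cache")
index = load_cache(work / "cache")  # later runs start here
print(f"cached and reloaded {len(index)} terms")

label = truth.queries[0].query
typo = corrupt_label(label, n_edits=1, seed=5)
print(f"\ntrue label: {label!r}\nquery:      {typo!r}\n")

for mapper in ("tfidf",) + SYNTACTIC_METRICS:
    table = map_terms([typo], index, MapperConfig(mapper=mapper))
    top = table.top_ranked().get(typo)
    hit = "ok " if top and top.term_iri == truth.queries[0].true_iri else "MISS"
    print(f"{mapper:12} {hit} {top.term_label if top else '-':34} {top.score if top else 0:.4f}")
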