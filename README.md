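# ontoground

Map free-text descriptions of biomedical entities — disease names,
phenotypes, cell types — to controlled terms in OWL ontologies, and
evaluate generated mappings against human-verified benchmark mapping sets.

Metadata attached to biomedical datasets is full of syntactically different
strings for the same concept ("cardiac failure", "heart failure",
"myocardial failure"). Grounding such strings to a controlled vocabulary
like the Experimental Factor Ontology (EFO) or MONDO makes the data
findable and integrable. `ontoground` is a library (with a thin CLI) for
doing this in bulk: it loads a target ontology, indexes every term's labels
and exact synonyms, and scores candidate matches for each input string.

## Methods at a glance

**TF-IDF n-gram mapper.** Each normalized string *s* (lowercased, NFC,
whitespace-collapsed — no stop-word removal, so "non-hodgkin's lymphoma"
keeps its negation) is padded with one space on each side and decomposed
into character *n*-grams (default *n* = 3). Strings become TF-IDF vectors
over the shared n-gram vocabulary,

&nbsp;&nbsp;&nbsp;&nbsp;w(t, d) = tf(t, d) · [ ln((1 + N)/(1 + df(t))) + 1 ],

ℓ²-normalized, and a query q is scored against every ontology name d by
cosine similarity cos(q, d) = q·d ∈ [0, 1]. The whole batch is one sparse
matrix product, so tens of thousands of queries map in seconds. Per query,
candidate terms keep their best-scoring name, are ranked by score (ties by
IRI), truncated to `max_mappings` (default 3) and filtered at `min_score`
(default 0.3); queries with no surviving candidate are reported as
unmapped.

**Syntactic mappers.** Pairwise normalized similarities: Levenshtein
(1 − d/max|·|), Indel (1 − d/(|a|+|b|)), Jaro, Jaro–Winkler (prefix scale
0.1, max prefix 4) and Jaccard over padded character trigram sets. Same
ranking contract as TF-IDF.

**Web annotators.** Thin clients for the BioPortal Annotator (every
annotation scored 1.0; the service reports no confidence) and Zooma
(confidence mapped HIGH = 1.0, GOOD = 0.75, MEDIUM = 0.5, LOW = 0.25),
with retry/backoff and per-source failure downgrading. They require
network access and are tested only against recorded responses.

**Mapping categorization.** Given a tool mapping T and a human-verified
mapping H for the same input, T is categorized via the subclass hierarchy
as **Same** (T = H), **MoreSpecific** (T ⊑ H), **MoreGeneral** (H ⊑ T),
**Sibling** (T and H share a direct superclass), else **Unrelated** — with
precedence in that order. Benchmark sets are first filtered to inputs with
exactly one distinct benchmark term. Entailment is approximated by the
transitive closure of asserted `rdfs:subClassOf` edges; a reasoner can be
plugged in as a load-time hook.

## Worked example

```python
from ontoground import MapperConfig, load_ontology, map_terms
from ontoground.fixtures import table2_mirror_ontology
from pathlib import Path; import tempfile

doc, _ = table2_mirror_ontology()          # bundled 17-term disease ontology
owl = Path(tempfile.mkdtemp()) / "diseases.owl"; owl.write_text(doc)
index = load_ontology(str(owl))

table = map_terms(["heart attack", "Hayfever or allergic rhinitis",
                   "cronic bronchitis", "zzqx"], index, MapperConfig(max_mappings=2))
for row in table.rows:
    print(f"{row.source.text!r:38} -> {row.term_label:28} {row.term_curie:14} {row.score:.4f}")
```

prints

```
'heart attack'                         -> myocardial infarction        MONDO:0005068  1.0000
'Hayfever or allergic rhinitis'        -> allergic rhinitis            EFO:0005854    0.7027
'Hayfever or allergic rhinitis'        -> seasonal allergic rhinitis   EFO:0003956    0.5363
'cronic bronchitis'                    -> chronic bronchitis           EFO:0006505    0.8352
```

"heart attack" scores 1.0 via the exact synonym of the term labeled
"myocardial infarction" — label-only matching would miss it. The typo'd
"cronic bronchitis" still ranks the right term first, and "zzqx" ends up
in `table.unmapped`. The `examples/` directory contains short runnable
scripts for mapping, caching + syntactic mappers, and benchmark
categorization; the CLI mirrors the library:

```bash
ontoground map -s terms.txt -t ontology.owl -o mappings.csv --incl-unmapped
ontoground cache -t ontology.owl -o efo_cache/
ontoground compare --table mappings.csv --benchmark bench.tsv -t ontology.owl
ontoground fixture --n-terms 100 --seed 7 -o toy.owl
```

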