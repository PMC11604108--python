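# Methods

## The mapping problem

Given a free-text description of a biomedical entity (a "source term") and
a target ontology in OWL, produce a ranked list of candidate ontology terms
with similarity scores in [0, 1]. The package also implements the
complementary evaluation step: categorizing a tool-generated mapping
against a human-verified one using the ontology's class hierarchy.

## Ontology processing

Ontologies are parsed with rdflib from RDF/XML or Turtle, from a local
path or URL. Per term the loader extracts:

* labels: `rdfs:label`, `skos:prefLabel`;
* exact synonyms: `oboInOwl:hasExactSynonym`, the NCI Thesaurus synonym
  property `P90`, EFO's `alternative_term`;
* broad synonyms (`oboInOwl:hasBroadSynonym`), only when requested —
  broad synonyms name more general concepts and dilute precision;
* definitions: `skos:definition`, `IAO:0000115` (kept for display, not
  used in matching);
* hierarchy: asserted `rdfs:subClassOf` (`rdfs:subPropertyOf` for
  properties) restricted to named parents; anonymous superclass
  expressions (OWL restrictions) are skipped and counted. Children and
  instances are derived as inverses.

Deprecation: a term is deprecated iff `owl:deprecated="true"` or it is
asserted below `oboInOwl:ObsoleteClass`. Deprecated terms are loaded and
flagged — the categorizer must be able to see them, because benchmark sets
do point at obsolete terms — but excluded from the matchable corpus unless
`include_deprecated` is set.

A term with no label and no synonym receives a fallback name derived from
its IRI fragment (underscores and camelCase split to spaces), so every
term is matchable. CURIEs are derived from the OBO-PURL pattern
(`.../obo/PREFIX_LOCAL` → `PREFIX:LOCAL`) and the EFO pattern; other IRIs
print in full.

Reasoning is off by default. `LoadConfig(apply_reasoning=True)` together
with a `reasoner` callable lets a caller assert inferred subclass edges on
the parsed graph before extraction; the core stays deterministic and
dependency-free. Multiple labels are all kept; the lexicographically first
`rdfs:label` is the display label (the underlying RDF graph API does not
expose document order, so a deterministic order was chosen instead).
Imports are processed as merged by the parser.

`ancestors(iri)` is the reflexive-free transitive closure over direct
parents, computed by iterative expansion (cycle-safe: a term is its own
ancestor only if it lies on a subclass cycle) and cached per index. A
loaded index round-trips through a JSON cache directory
(`metadata.json` + `terms.json`, refused across major format versions).

## Normalization and matching

`normalize` lowercases, applies unicode NFC, collapses whitespace and
strips — nothing else. Deliberately there is no stop-word removal or
token filtering: removing "non" turns "non-hodgkin's lymphoma" into its
own negation, a known failure mode of tokenizing matchers.

**TF-IDF mapper.** Documents are the normalized labels and exact synonyms
of matchable terms, each padded with one leading/trailing space and
decomposed into character n-grams of length `ngram_size` (default 3:
robust to single typos and word-order changes while keeping the vocabulary
small). Vectors use the smooth-IDF convention
idf(t) = ln((1+N)/(1+df(t))) + 1 with raw counts and ℓ² normalization
(scikit-learn's `TfidfVectorizer`); cosine similarity is the sparse matrix
product of the two ℓ²-normalized matrices. By default the IDF is fitted on
the union of ontology names and the query batch so both sides share one
vocabulary (`tfidf_fit="union"`); this makes scores mildly batch-dependent,
and `tfidf_fit="ontology"` is available when batch-independent scores
matter more than query-side vocabulary coverage. A query shorter than the
n-gram size (after padding) has no features and is reported unmapped, not
an error.

**Ranking contract** (shared by all mappers): per query, each candidate
term keeps its best-scoring name (ties prefer label over exact over broad
synonym, then the lexicographically smaller name); terms are ranked by
descending score with exact ties broken by IRI; the list is truncated to
`max_mappings` (default 3 — small output, but alternates visible) and
filtered at `min_score` (default 0.3; structural zeros never match). This
makes output deterministic and truncation prefix-monotone.

**Syntactic metrics.** The named distances are normalized to similarities:
`levenshtein` 1 − d/max(|a|,|b|); `indel` 1 − d/(|a|+|b|) with
d = |a|+|b|−2·LCS; `jaro`/`jarowinkler` in their standard forms (match
window ⌊max/2⌋−1, transpositions halved with integer division, Winkler
prefix scale 0.1 over at most 4 characters); `jaccard` |A∩B|/|A∪B| over
padded character trigram sets. Padding guarantees every non-empty string
has at least one trigram, so sim(x, x) = 1 holds even for 1–2 character
strings. Conventions: two empty strings are identical (1.0); one empty
string matches nothing (0.0). The underlying literature names these
metrics without fixing normalizations or token units; the forms above are
the standard ones and are pinned by the test oracles.

**Web annotators.** BioPortal's annotator returns no confidence, so every
annotation is scored 1.0; Zooma's categorical confidence is mapped
monotonically (HIGH 1.0, GOOD 0.75, MEDIUM 0.5, LOW 0.25 — any monotone
embedding works with the default `min_score`, this one is simply
documented and fixed). Requests retry 3 times with exponential backoff;
a source that still fails becomes an unmapped entry with a reason rather
than aborting the batch. The transport is injectable, and the test suite
exercises these clients exclusively against recorded responses.

## Output schema

Mapping tables are CSV/TSV with `# key: value` metadata lines, then
columns Source Term ID, Source Term, Mapped Term Label, Mapped Term CURIE,
Mapped Term IRI, Mapping Score (6 decimals), Mapper, Mapping Type, Tags.
Mapping Type is Exact/Broad/Narrow (the SKOS mappingRelation
subproperties), default Exact. Unmapped sources appear with empty mapped
fields when requested. Omitting the timestamp (`--no-timestamp`) makes
runs byte-identical. SSSOM-style TSV (`subject_id`/`object_id`, optional
`subject_label`) is accepted on read and yields mappings tagged
`mapper="external"` — this is how benchmark sets come in.

## Categorization

For tool term T and benchmark term H: Same if T = H; MoreSpecific if
H ∈ ancestors(T); MoreGeneral if T ∈ ancestors(H); Sibling if T and H
share a *direct* parent; else Unrelated — evaluated in that order.
Precedence resolves pairs satisfying several clauses (a direct parent that
is also a co-child in a diamond is MoreGeneral, not Sibling): specificity
relations carry more information than the sibling relation. Only asserted
direct parents feed the sibling test. Benchmark inputs are first reduced
to those with exactly one distinct benchmark term; duplicates collapse,
ambiguous inputs are counted and excluded. Inputs the tool left unmapped
are tallied separately, never as Unrelated, and benchmark entries pointing
at deprecated terms are kept but counted (`deprecated_benchmark`).

## Synthetic fixtures

`generate_toy_ontology(FixtureSpec)` emits a rooted DAG of classes as
RDF/XML: every non-root class gets one parent among earlier classes with
spare capacity (`max_children`, default 4) and with probability 0.15 a
second parent, producing the diamonds the categorizer tests need. Defaults
— 50 terms, synonym rate 0.5, deprecated rate 0 — give a small ontology
with the annotation mix (labels everywhere, synonyms on about half the
terms) typical of curated disease ontologies. Labels are drawn from a
seeded pseudo-biomedical vocabulary (modifier + stem/suffix or real
disease token + optional anatomy phrase) rather than uniform random
strings, so n-gram statistics are non-degenerate and cosine scores spread
realistically. Labels are globally unique and synonyms never collide with
labels, which makes the refind property exact by construction. The
document is produced by string templating, not a graph serializer, so one
spec yields byte-identical files; the loader then parses it with rdflib,
keeping the generator/loader round trip a genuine two-route check.

`corrupt_label` applies seeded single-character substitutions (always to a
different character), insertions or deletions, so the result is within
Levenshtein distance `n_edits` of the original. `table2_mirror_ontology`
is a hand-written 17-class disease ontology whose hierarchy encodes one
known example of each category relationship between real disease terms,
plus a deprecated duplicate term and a label/synonym pair ("myocardial
infarction" / "heart attack") for synonym-matching checks.

What the fixtures do **not** emulate: the size (tens of thousands of
terms), synonym density skew, multiple-inheritance depth or
cross-ontology term reuse of a production ontology like EFO. Passing
tests establish algorithmic correctness against oracles at small scale,
not mapping accuracy on real benchmark corpora.

## Verification strategy and problem sizes

Every non-trivial computation is checked against an independent
brute-force oracle living in the test suite: dense numpy TF-IDF + cosine
over explicit n-gram counts, full-matrix dynamic programming for
Levenshtein/indel (plus an external aligner, edlib, for the distance
itself), explicit set construction for Jaccard, a two-pass reference Jaro,
and breadth-first search for ancestor closures and categorization.
`scripts/acceptance.py` re-runs these comparisons from scratch at fixed
sizes — 10 fixtures of 50–185 terms with 50 queries each for TF-IDF, 1000
string pairs per metric, a 100-term fixture with one edit per query for
typo robustness, exhaustive ordered pairs on 10–17-term ontologies for
categorization — sizes at which the dense oracles are exact and the whole
script completes in seconds.

## Known limitations

* Entailment is structural: without a plugged-in reasoner, inferred
  subsumptions (e.g. via equivalence axioms or property restrictions) are
  invisible to both the ancestor closure and the categorizer.
* Union-mode TF-IDF scores shift slightly across query batches; use
  `tfidf_fit="ontology"` for batch-stable scores.
* The web mappers depend on external service schemas that can drift; only
  the recorded-response contract is under test.
* No concept recognition inside long passages: inputs are discrete entity
  descriptions, and no embedding/LLM mapper is provided.
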