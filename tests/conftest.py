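import pytest

from ontoground import LoadConfig, load_ontology
from ontoground.fixtures import FixtureSpec, generate_toy_ontology, table2_mirror_ontology


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """60-term seeded toy ontology: (index, ground truth, owl path)."""
    spec = FixtureSpec(n_terms=60, max_children=4, synonym_rate=0.5, deprecated_rate=0.1, seed=3)
    doc, truth = generate_toy_ontology(spec)
    path = tmp_path_factory.mktemp("toy") / "toy.owl"
    path.write_text(doc, encoding="utf-8")
    index = load_ontology(str(path), LoadConfig(include_broad_synonyms=True))
    return index, truth, path


@pytest.fixture(scope="session")
def mirror(tmp_path_factory):
    """Hand-written disease ontology with known category relationships."""
    doc, expected = table2_mirror_ontology()
    path = tmp_path_factory.mktemp("mirror") / "mirror.owl"
    path.write_text(doc, encoding="utf-8")
    index = load_ontology(str(path))
    return index, expected, path
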