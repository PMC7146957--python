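import pathlib
import sys

import pytest

sys.path.insert(0, str(pathlib.Path(__file__).parent))  # for oracles.py

from goclust import enrichment, fixtures, ontology


def make_term(go_id, genes, p=0.01, n=100, description="", namespace="unknown"):
    return enrichment.EnrichedTerm(
        go_id=go_id, description=description or go_id, p_value=p,
        genes=frozenset(g.upper() for g in genes), n=n, namespace=namespace)


def make_list(terms):
    return enrichment.EnrichmentList(terms=tuple(terms))


@pytest.fixture(scope="session")
def chain_obo_graph():
    """root -> A -> B chain plus a diamond (root -> D -> E, root -> E),
    a part_of parent, an alt_id and an obsolete term."""
    text = """\
format-version: 1.2
data-version: test/2026-01-01

[Term]
id: GO:0000001
name: biological_process
namespace: biological_process

[Term]
id: GO:0000002
name: level one
namespace: biological_process
is_a: GO:0000001 ! biological_process

[Term]
id: GO:0000003
name: level two
namespace: biological_process
alt_id: GO:0000103
is_a: GO:0000002

[Term]
id: GO:0000004
name: diamond mid
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000005
name: diamond bottom
namespace: biological_process
is_a: GO:0000004
is_a: GO:0000001

[Term]
id: GO:0000006
name: has part_of parent
namespace: biological_process
is_a: GO:0000002
relationship: part_of GO:0000004

[Term]
id: GO:0000007
name: gone
namespace: biological_process
is_obsolete: true
"""
    return ontology.parse_obo_text(text, source="chain fixture")


@pytest.fixture(scope="session")
def bundle_single():
    return fixtures.generate_fixture(fixtures.PlantedDesign(seed=1))


@pytest.fixture(scope="session")
def bundle_two_level():
    return fixtures.generate_fixture(fixtures.PlantedDesign(seed=1, levels=2))


def load_bundle(bundle, tmp_path):
    """Materialize a fixture bundle and read it back through the file readers."""
    graph = ontology.parse_obo_text(bundle.obo_text)
    tmp_path.mkdir(parents=True, exist_ok=True)
    path = tmp_path / "enrichment.tsv"
    path.write_text(bundle.enrichment_text, encoding="utf-8")
    elist = enrichment.read_enrichment(path)
    return graph, elist


@pytest.fixture()
def loaded_single(bundle_single, tmp_path):
    return load_bundle(bundle_single, tmp_path)


@pytest.fixture()
def loaded_two_level(bundle_two_level, tmp_path):
    return load_bundle(bundle_two_level, tmp_path)
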