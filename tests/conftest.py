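import os

import pytest

from hoplite.canonicalize import build_equivalence_map
from hoplite.index import build_index, build_subclass_closure
from hoplite.kgx import Graph, KnowledgeEdge, KnowledgeNode
from hoplite.semantic_model import load_semantic_model

DATA_DIR = os.path.join(os.path.dirname(__file__), "data")
MINI_MODEL_PATH = os.path.join(DATA_DIR, "mini_model.yaml")


@pytest.fixture(scope="session")
def mini_model_path():
    return MINI_MODEL_PATH


@pytest.fixture(scope="session")
def mini_model():
    return load_semantic_model(MINI_MODEL_PATH)


def make_node(nid, categories, name="", equivalents=(), **props):
    return KnowledgeNode(id=nid, name=name or nid, categories=list(categories),
                         equivalent_identifiers=list(equivalents),
                         properties=dict(props))


def make_edge(eid, subject, predicate, object_, **props):
    return KnowledgeEdge(id=eid, subject=subject, object=object_,
                         predicate=predicate, properties=dict(props))


def make_graph(nodes, edges):
    g = Graph()
    for n in nodes:
        g.nodes[n.id] = n
    for e in edges:
        g.edges[e.id] = e
    return g


@pytest.fixture(scope="session")
def drug_graph():
    """Small drug/protein/disease graph exercising every reasoning feature.

    - acetaminophen (CHEBI id, equivalent DRUGBANK id) physically interacts
      with two proteins (one edge stored in each direction);
    - a non-canonical treated_by edge that must be flipped into treats;
    - a subclass chain pain <- headache <- migraine;
    - an unrelated gene-pathway edge via a canonical predicate.
    """
    nodes = [
        make_node("CHEBI:46195", ["Drug"], name="acetaminophen",
                  equivalents=["DRUGBANK:DB00316"]),
        make_node("UniProtKB:P23219", ["Protein"], name="PTGS1"),
        make_node("UniProtKB:P35354", ["Protein"], name="PTGS2"),
        make_node("MONDO:0021166", ["Disease"], name="pain disorder"),
        make_node("MONDO:0005301", ["Disease"], name="headache disorder"),
        make_node("MONDO:0005277", ["Disease"], name="migraine"),
        make_node("NCBIGene:5743", ["Gene"], name="PTGS2 gene"),
        make_node("TEST:pathway1", ["Pathway"], name="prostaglandin synthesis"),
    ]
    edges = [
        make_edge("e1", "CHEBI:46195", "physically_interacts_with",
                  "UniProtKB:P23219", primary_knowledge_source="infores:drugcentral",
                  publications=["PMID:1", "PMID:2"]),
        make_edge("e2", "UniProtKB:P35354", "physically_interacts_with",
                  "CHEBI:46195", primary_knowledge_source="infores:drugcentral"),
        make_edge("e3", "MONDO:0021166", "treated_by", "CHEBI:46195",
                  primary_knowledge_source="infores:chembl"),
        make_edge("e4", "MONDO:0005301", "subclass_of", "MONDO:0021166",
                  primary_knowledge_source="infores:mondo"),
        make_edge("e5", "MONDO:0005277", "subclass_of", "MONDO:0005301",
                  primary_knowledge_source="infores:mondo"),
        make_edge("e6", "NCBIGene:5743", "participates_in", "TEST:pathway1",
                  primary_knowledge_source="infores:reactome"),
    ]
    return make_graph(nodes, edges)


@pytest.fixture(scope="session")
def drug_engine(drug_graph, mini_model):
    """(index, model, subclass, eqmap) built over the drug fixture graph."""
    eqmap = build_equivalence_map(drug_graph, prefix_priority=["CHEBI", "DRUGBANK"])
    subclass = build_subclass_closure(drug_graph)
    index = build_index(drug_graph, mini_model)
    return index, mini_model, subclass, eqmap
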