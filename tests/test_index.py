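"""Adjacency-index construction, lookup, subclass closure and persistence."""

import json
import os

import networkx as nx
import pytest

from hoplite.canonicalize import build_equivalence_map
from hoplite.index import (SnapshotCorruptError, SnapshotNotFoundError,
                           SnapshotVersionError, build_index,
                           build_subclass_closure, load_index,
                           lookup_neighbors, save_index)
from hoplite.kgx import Graph
from hoplite.query import answer_query, parse_query_graph, result_triples
from hoplite.synth import SynthSpec, generate_graph

from conftest import make_edge, make_graph, make_node


def test_empty_graph_builds_empty_index(mini_model):
    index = build_index(Graph(), mini_model)
    assert index.n_edges == 0 and not index.node_store


def test_symmetric_edge_retrievable_from_both_ends(mini_model):
    g = make_graph(
        [make_node("A:1", ["Drug"]), make_node("B:1", ["Protein"])],
        [make_edge("e1", "A:1", "physically_interacts_with", "B:1")])
    index = build_index(g, mini_model)
    for node, neighbor in (("A:1", "B:1"), ("B:1", "A:1")):
        for pred in ("physically_interacts_with", "interacts_with", "related_to"):
            assert lookup_neighbors(index, node, None, {pred}, "out") == \
                {(neighbor, "e1")}, (node, pred)


def test_noncanonical_edge_stored_flipped(mini_model):
    g = make_graph(
        [make_node("C:1", ["Disease"]), make_node("D:1", ["Drug"])],
        [make_edge("e1", "C:1", "treated_by", "D:1")])
    index = build_index(g, mini_model)
    stored = index.edge_store["e1"]
    assert (stored.subject, stored.predicate, stored.object) == ("D:1", "treats", "C:1")
    assert "e1" in index.flipped_edges
    # retrievable outward from the drug under treats and its ancestors
    assert lookup_neighbors(index, "D:1", None, {"treats"}, "out") == {("C:1", "e1")}
    assert lookup_neighbors(index, "D:1", None, {"affects"}, "out") == {("C:1", "e1")}
    assert lookup_neighbors(index, "C:1", None, {"treats"}, "in") == {("D:1", "e1")}


def test_hierarchy_expansion_covers_ancestor_categories(mini_model):
    g = make_graph(
        [make_node("A:1", ["Drug"]), make_node("B:1", ["Protein"])],
        [make_edge("e1", "A:1", "affects", "B:1")])
    index = build_index(g, mini_model)
    for cat in ("Protein", "BiologicalEntity", "NamedThing"):
        assert lookup_neighbors(index, "A:1", {cat}, None, "out") == {("B:1", "e1")}
    assert lookup_neighbors(index, "A:1", {"Disease"}, None, "out") == set()


def test_unknown_predicate_indexed_under_root(mini_model):
    g = make_graph(
        [make_node("A:1", ["Drug"]), make_node("B:1", ["Protein"])],
        [make_edge("e1", "A:1", "frobnicates", "B:1")])
    index = build_index(g, mini_model)
    assert index.build_meta["unknown_predicate_edges"] == 1
    assert lookup_neighbors(index, "A:1", None, {"related_to"}, "out") == {("B:1", "e1")}
    assert lookup_neighbors(index, "A:1", None, {"affects"}, "out") == set()


def test_lookup_edge_cases(mini_model, drug_engine):
    index = drug_engine[0]
    assert lookup_neighbors(index, "NO:SUCH", None, None, "any") == set()
    assert lookup_neighbors(index, "CHEBI:46195", None, set(), "any") == set()
    assert lookup_neighbors(index, "CHEBI:46195", set(), None, "any") == set()


def test_expansion_soundness_exhaustive(drug_engine):
    """Every stored pair appears under every ancestor predicate/category."""
    index, model = drug_engine[0], drug_engine[1]
    for node, by_cat in index.adj.items():
        for cat, by_pred in by_cat.items():
            for pred, by_dir in by_pred.items():
                for direction, pairs in by_dir.items():
                    for anc in model.predicate_ancestors(pred):
                        for cat_anc in model.category_ancestors(cat):
                            assert pairs <= index.adj[node][cat_anc][anc][direction]


def test_lookup_matches_brute_force_scan(mini_model):
    """Index lookups equal a naive scan with on-the-fly expansion."""
    import random
    for seed in range(20):
        g, model, _, _ = generate_graph(SynthSpec(seed=seed, n_nodes=30, n_edges=80))
        index = build_index(g, model)
        rng = random.Random(seed)
        for _ in range(10):
            node = rng.choice(sorted(g.nodes))
            pred = rng.choice(sorted(model.predicates))
            expected = set()
            for e in g.edges.values():
                canonical, flipped = (model.canonical_form(e.predicate)
                                      if model.has_predicate(e.predicate)
                                      else (model.root_predicate, False))
                if pred not in model.predicate_ancestors(canonical):
                    continue
                s, o = (e.object, e.subject) if flipped else (e.subject, e.object)
                if model.is_symmetric(canonical):
                    if node in (s, o):
                        other = o if node == s else s
                        expected.add((other, e.id))
                elif node == s:
                    expected.add((o, e.id))
                elif node == o:
                    expected.add((s, e.id))
            got = lookup_neighbors(index, node, None, {pred}, "any")
            assert got == expected, (seed, node, pred)


# -- subclass closure -------------------------------------------------------


def subclass_graph(pairs):
    nodes = {n for p in pairs for n in p}
    return make_graph([make_node(n, ["NamedThing"]) for n in sorted(nodes)],
                      [make_edge(f"e{i}", child, "subclass_of", parent)
                       for i, (child, parent) in enumerate(pairs)])


def test_no_subclass_edges_empty_closure(drug_engine):
    g = make_graph([make_node("A:1", ["Drug"])], [])
    closure = build_subclass_closure(g)
    assert closure.descendants_of == {}


def test_chain_closure():
    g = subclass_graph([("C:c", "C:b"), ("C:b", "C:a")])
    closure = build_subclass_closure(g)
    assert closure.descendants("C:a") == {"C:b", "C:c"}
    assert closure.descendants("C:b") == {"C:c"}
    assert closure.descendants("C:c") == set()


def test_two_cycle_terminates_without_self_membership():
    g = subclass_graph([("C:x", "C:y"), ("C:y", "C:x")])
    closure = build_subclass_closure(g)
    assert closure.descendants("C:x") == {"C:y"}
    assert closure.descendants("C:y") == {"C:x"}


def test_closure_matches_networkx_reachability():
    """Closure equals independent reachability, including through cycles."""
    pairs = [("N:b", "N:a"), ("N:c", "N:b"), ("N:d", "N:b"), ("N:e", "N:d"),
             ("N:a", "N:e"),  # cycle a->e->d->b->a (reversed edges)
             ("N:f", "N:c")]
    g = subclass_graph(pairs)
    closure = build_subclass_closure(g)
    dag = nx.DiGraph()
    dag.add_edges_from((parent, child) for child, parent in pairs)
    for node in dag.nodes:
        expected = nx.descendants(dag, node) - {node}
        assert closure.descendants(node) == expected, node


def test_max_depth_limits_chaining():
    g = subclass_graph([("C:c", "C:b"), ("C:b", "C:a")])
    closure = build_subclass_closure(g, max_depth=1)
    assert closure.descendants("C:a") == {"C:b"}


def test_external_edges_unioned():
    g = subclass_graph([("C:b", "C:a")])
    extra = [make_edge("x1", "C:c", "subclass_of", "C:b")]
    closure = build_subclass_closure(g, external_edges=extra)
    assert closure.descendants("C:a") == {"C:b", "C:c"}


# -- persistence ------------------------------------------------------------


def roundtrip(tmp_path, index, subclass, eqmap):
    target = str(tmp_path / "snapshot")
    save_index(index, subclass, eqmap, target)
    return load_index(target), target


def test_save_load_observational_identity(tmp_path, drug_graph, drug_engine):
    index, model, subclass, eqmap = drug_engine
    (index2, subclass2, eqmap2), _ = roundtrip(tmp_path, index, subclass, eqmap)
    queries = [
        {"nodes": {"n0": {"ids": ["CHEBI:46195"]}, "n1": {"categories": ["Protein"]}},
         "edges": {"e0": {"subject": "n0", "object": "n1",
                          "predicates": ["interacts_with"]}}},
        {"nodes": {"n0": {"ids": ["MONDO:0021166"]}, "n1": {}},
         "edges": {"e0": {"subject": "n1", "object": "n0",
                          "predicates": ["treats"]}}},
    ]
    for qg in queries:
        q = parse_query_graph({"message": {"query_graph": qg}})
        before = answer_query(q, index, model, subclass, eqmap)
        after = answer_query(q, index2, model, subclass2, eqmap2)
        assert before == after
        assert result_triples(before)


def test_save_empty_index_loads(tmp_path, mini_model):
    from hoplite.canonicalize import EquivalenceMap
    from hoplite.index import SubclassIndex
    index = build_index(Graph(), mini_model)
    (index2, _, _), _ = roundtrip(tmp_path, index, SubclassIndex(), EquivalenceMap())
    assert index2.n_edges == 0


def test_snapshot_error_taxonomy(tmp_path, drug_engine):
    index, _, subclass, eqmap = drug_engine
    with pytest.raises(SnapshotNotFoundError):
        load_index(str(tmp_path / "nowhere"))

    target = str(tmp_path / "snap")
    save_index(index, subclass, eqmap, target)

    manifest_path = os.path.join(target, "manifest.json")
    manifest = json.load(open(manifest_path))
    manifest["format_version"] = 999
    json.dump(manifest, open(manifest_path, "w"))
    with pytest.raises(SnapshotVersionError, match="999"):
        load_index(target)

    manifest["format_version"] = 1
    json.dump(manifest, open(manifest_path, "w"))
    with open(os.path.join(target, "edges.json"), "a") as fh:
        fh.write(" ")
    with pytest.raises(SnapshotCorruptError, match="checksum"):
        load_index(target)


def test_build_deterministic(mini_model):
    g, model, _, _ = generate_graph(SynthSpec(seed=3))
    i1 = build_index(g, model)
    i2 = build_index(g, model)
    assert i1.adj == i2.adj
    assert list(i1.edge_store) == list(i2.edge_store)
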