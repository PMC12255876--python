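"""Synthetic knowledge graphs with planted structure, plus the brute-force oracle.

The generator emits KGX graphs (both dialects) together with a matching
semantic-model file and a ground-truth record of everything it planted:
random category/predicate hierarchies of controlled depth, a controlled mix
of symmetric predicates and canonical/non-canonical inverse pairs,
equivalence clusters planted through ``equivalent_identifiers``, and
subclass chains planted as ``subclass_of`` edges.  A fixed seed yields
byte-identical output; independent sub-streams per concern (topology,
hierarchy, clusters, ...) keep draws stable when one concern's logic grows.

``brute_force_answer`` is the referee for the indexed engine: a deliberately
naive re-statement of one-hop matching semantics that walks hierarchies,
equivalence and subclass reachability on the fly, edge by edge.  It shares no
expansion code with the index or query modules.
"""

from __future__ import annotations

import json
import os
import random
from collections import deque
from dataclasses import dataclass, field

import yaml

from .canonicalize import EquivalenceMap
from .kgx import Graph, KnowledgeEdge, KnowledgeNode, write_graph
from .query import QueryGraph
from .semantic_model import SemanticModel, load_semantic_model, strip_prefix

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "generate_graph",
    "generate_kg",
    "random_query_graph",
    "brute_force_answer",
]

_SOURCES = ["infores:alpha", "infores:beta", "infores:gamma"]


class SpecError(ValueError):
    """The generation spec is infeasible."""


@dataclass
class SynthSpec:
    n_nodes: int = 50
    n_edges: int = 150
    category_tree_depth: int = 3
    predicate_tree_depth: int = 3
    symmetric_fraction: float = 0.2
    inverse_pair_fraction: float = 0.3
    equivalence_cluster_rate: float = 0.15
    subclass_chain_count: int = 2
    subclass_chain_length: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("symmetric_fraction", "inverse_pair_fraction",
                     "equivalence_cluster_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_nodes", "n_edges", "subclass_chain_count",
                     "subclass_chain_length"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be non-negative")
        if self.subclass_chain_count * self.subclass_chain_length > self.n_nodes:
            raise SpecError("subclass chains need more nodes than the spec provides")


@dataclass
class GroundTruth:
    model: SemanticModel
    clusters: list[list[str]] = field(default_factory=list)
    subclass_chains: list[list[str]] = field(default_factory=list)
    edges: list[tuple[str, str, str]] = field(default_factory=list)


def _stream(spec: SynthSpec, purpose: str) -> random.Random:
    return random.Random(f"{spec.seed}:{purpose}")


def _make_model(spec: SynthSpec) -> tuple[dict, SemanticModel]:
    """Random category/predicate hierarchies honoring the spec's fractions."""
    rng = _stream(spec, "hierarchy")
    categories: dict[str, dict] = {"NamedThing": {}}
    level = ["NamedThing"]
    for depth in range(spec.category_tree_depth):
        next_level = []
        for i in range(2):
            name = f"Cat{depth}{chr(65 + i)}"
            categories[name] = {"parents": [rng.choice(level)]}
            next_level.append(name)
        level = next_level

    predicates: dict[str, dict] = {"related_to": {},
                                   "subclass_of": {"parents": ["related_to"]}}
    level = ["related_to"]
    counter = 0
    for depth in range(spec.predicate_tree_depth):
        next_level = []
        for _ in range(2):
            parent = rng.choice(level)
            name = f"pred_{counter}"
            counter += 1
            roll = rng.random()
            if roll < spec.symmetric_fraction:
                predicates[name] = {"parents": [parent], "symmetric": True}
            elif roll < spec.symmetric_fraction + spec.inverse_pair_fraction:
                inv = f"{name}_of"
                predicates[name] = {"parents": [parent], "canonical": True,
                                    "inverse": inv}
                predicates[inv] = {"parents": [parent], "inverse": name}
            else:
                predicates[name] = {"parents": [parent]}
            next_level.append(name)
        level = next_level

    raw = {"categories": categories, "predicates": predicates,
           "category_prefixes": {"NamedThing": ["TEST"]}}
    return raw, _model_from_dict(raw)


def _model_from_dict(raw: dict) -> SemanticModel:
    import tempfile
    with tempfile.NamedTemporaryFile("w", suffix=".yaml", delete=False) as fh:
        yaml.safe_dump(raw, fh)
        path = fh.name
    try:
        return load_semantic_model(path)
    finally:
        os.unlink(path)


def generate_graph(spec: SynthSpec) -> tuple[Graph, SemanticModel, GroundTruth, dict]:
    """Generate an in-memory graph, model and ground truth from *spec*."""
    spec.validate()
    raw_model, model = _make_model(spec)
    truth = GroundTruth(model=model)
    graph = Graph(provenance={"synthetic": True, "seed": spec.seed})

    cat_rng = _stream(spec, "node-categories")
    all_cats = sorted(model.categories)
    node_ids = [f"TEST:n{i:04d}" for i in range(spec.n_nodes)]
    for nid in node_ids:
        cats = [cat_rng.choice(all_cats)]
        if cat_rng.random() < 0.2:
            extra = cat_rng.choice(all_cats)
            if extra not in cats:
                cats.append(extra)
        graph.nodes[nid] = KnowledgeNode(
            id=nid, name=f"concept {nid.split(':')[1]}", categories=cats)

    # equivalence clusters planted via mutual equivalent_identifiers
    cluster_rng = _stream(spec, "clusters")
    n_clustered = int(round(spec.n_nodes * spec.equivalence_cluster_rate))
    pool = list(node_ids)
    cluster_rng.shuffle(pool)
    pool = pool[:n_clustered]
    while len(pool) >= 2:
        size = min(len(pool), cluster_rng.choice([2, 2, 3]))
        members, pool = pool[:size], pool[size:]
        truth.clusters.append(sorted(members))
        for m in members:
            graph.nodes[m].equivalent_identifiers = sorted(
                x for x in members if x != m)

    # subclass chains planted as subclass_of edges (child -> parent)
    chain_rng = _stream(spec, "subclass")
    available = [n for n in node_ids]
    chain_rng.shuffle(available)
    edge_counter = 0
    for _ in range(spec.subclass_chain_count):
        length = spec.subclass_chain_length
        if length < 2 or len(available) < length:
            break
        chain, available = available[:length], available[length:]
        truth.subclass_chains.append(chain)
        for parent, child in zip(chain, chain[1:]):
            eid = f"e{edge_counter:05d}"
            edge_counter += 1
            graph.edges[eid] = KnowledgeEdge(
                id=eid, subject=child, object=parent, predicate="subclass_of",
                properties={"primary_knowledge_source": "infores:ontology"})
            truth.edges.append((child, "subclass_of", parent))

    # ordinary edges drawn uniformly over node pairs and non-subclass predicates
    edge_rng = _stream(spec, "edges")
    predicates = sorted(p for p in model.predicates
                        if p not in ("subclass_of",))
    for _ in range(spec.n_edges):
        if spec.n_nodes < 2:
            break
        subject, object_ = edge_rng.sample(node_ids, 2)
        predicate = edge_rng.choice(predicates)
        props: dict = {"primary_knowledge_source": edge_rng.choice(_SOURCES)}
        if edge_rng.random() < 0.4:
            n_pubs = edge_rng.randint(1, 3)
            props["publications"] = [
                f"PMID:{edge_rng.randint(1000, 99999)}" for _ in range(n_pubs)]
        if edge_rng.random() < 0.3:
            props["knowledge_level"] = edge_rng.choice(
                ["knowledge_assertion", "prediction"])
        eid = f"e{edge_counter:05d}"
        edge_counter += 1
        graph.edges[eid] = KnowledgeEdge(
            id=eid, subject=subject, object=object_, predicate=predicate,
            properties=props)
        truth.edges.append((subject, predicate, object_))
    return graph, model, truth, raw_model


def generate_kg(spec: SynthSpec, out_dir: str) -> dict:
    """Emit the generated KG in both KGX dialects plus schema and ground truth.

    Returns a map of artifact names to file paths.
    """
    graph, model, truth, raw_model = generate_graph(spec)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "nodes_tsv": os.path.join(out_dir, "nodes.tsv"),
        "edges_tsv": os.path.join(out_dir, "edges.tsv"),
        "nodes_jsonl": os.path.join(out_dir, "nodes.jsonl"),
        "edges_jsonl": os.path.join(out_dir, "edges.jsonl"),
        "schema": os.path.join(out_dir, "schema.yaml"),
        "ground_truth": os.path.join(out_dir, "ground_truth.json"),
    }
    write_graph(graph, paths["nodes_tsv"], paths["edges_tsv"], "tsv")
    write_graph(graph, paths["nodes_jsonl"], paths["edges_jsonl"], "jsonlines")
    with open(paths["schema"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw_model, fh, sort_keys=True)
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump({
            "clusters": truth.clusters,
            "subclass_chains": truth.subclass_chains,
            "edges": truth.edges,
        }, fh, sort_keys=True, indent=1)
    return paths


def random_query_graph(rng: random.Random, graph: Graph,
                       model: SemanticModel) -> dict:
    """Draw a random answerable one-hop query over *graph* (TRAPI dict form)."""
    node_ids = sorted(graph.nodes)
    predicates = sorted(model.predicates)
    categories = sorted(model.categories)

    pinned_ids = rng.sample(node_ids, min(len(node_ids), rng.choice([1, 1, 1, 2])))
    n0: dict = {"ids": pinned_ids}
    n1: dict = {}
    if rng.random() < 0.25 and len(node_ids) > 3:
        n1["ids"] = rng.sample(node_ids, rng.choice([1, 2, 4]))
    elif rng.random() < 0.6:
        n1["categories"] = [rng.choice(categories)]
    edge: dict = {"subject": "n0", "object": "n1"}
    if rng.random() < 0.5:
        edge = {"subject": "n1", "object": "n0"}
    if rng.random() < 0.8:
        edge["predicates"] = rng.sample(predicates, rng.choice([1, 1, 2]))
    if rng.random() < 0.2:
        edge["attribute_constraints"] = [{
            "id": "primary_knowledge_source",
            "operator": "==",
            "value": rng.choice(_SOURCES + ["infores:ontology"]),
            "not": rng.random() < 0.3,
        }]
    return {"message": {"query_graph": {
        "nodes": {"n0": n0, "n1": n1}, "edges": {"e0": edge}}}}


def star_graph(n_edges: int) -> tuple[Graph, SemanticModel]:
    """A hub node with *n_edges* distinct neighbors under one predicate.

    Engineered so that a single pinned query on the hub returns exactly
    *n_edges* answer edges; used to study how response time scales with
    answer size.
    """
    raw = {
        "categories": {"NamedThing": {}, "Neighbor": {"parents": ["NamedThing"]}},
        "predicates": {"related_to": {}, "linked_to": {"parents": ["related_to"]}},
    }
    model = _model_from_dict(raw)
    graph = Graph(provenance={"synthetic": True, "shape": "star"})
    graph.nodes["TEST:hub"] = KnowledgeNode(id="TEST:hub", name="hub",
                                            categories=["NamedThing"])
    for i in range(n_edges):
        nid = f"TEST:leaf{i:06d}"
        graph.nodes[nid] = KnowledgeNode(id=nid, name=f"leaf {i}",
                                         categories=["Neighbor"])
        graph.edges[f"e{i:06d}"] = KnowledgeEdge(
            id=f"e{i:06d}", subject="TEST:hub", object=nid,
            predicate="linked_to",
            properties={"primary_knowledge_source": "infores:synthetic"})
    return graph, model


DEFAULT_SCALING_SIZES = [10, 32, 100, 316, 1000, 3162, 10000, 31623, 100000]


def measure_scaling(sizes: list[int] | None = None,
                    repeats: int = 3) -> list[tuple[int, float]]:
    """Median one-hop response time (seconds) per answer size, on star graphs.

    The garbage collector is quiesced around each timed call so allocation
    spikes do not masquerade as asymptotic growth.
    """
    import gc
    import statistics
    import time

    from .canonicalize import build_equivalence_map
    from .index import build_index, build_subclass_closure
    from .query import answer_query, parse_query_graph

    points: list[tuple[int, float]] = []
    for n in sizes or DEFAULT_SCALING_SIZES:
        graph, model = star_graph(n)
        eqmap = build_equivalence_map(graph)
        subclass = build_subclass_closure(graph)
        index = build_index(graph, model)
        qgraph = parse_query_graph({"message": {"query_graph": {
            "nodes": {"n0": {"ids": ["TEST:hub"]}, "n1": {}},
            "edges": {"e0": {"subject": "n0", "object": "n1",
                             "predicates": ["linked_to"]}},
        }}})
        times = []
        for _ in range(repeats):
            gc.collect()
            gc.disable()
            try:
                t0 = time.perf_counter()
                response = answer_query(qgraph, index, model, subclass, eqmap)
                times.append(time.perf_counter() - t0)
            finally:
                gc.enable()
            assert len(response["message"]["results"]) == n
            del response
        points.append((n, statistics.median(times)))
    return points


def scaling_slope(points: list[tuple[int, float]]) -> float:
    """Slope of the log-log regression of response time on answer edge count."""
    import numpy as np

    log_n = np.log10([p[0] for p in points])
    log_t = np.log10([p[1] for p in points])
    return float(np.polyfit(log_n, log_t, 1)[0])


# ---------------------------------------------------------------------------
# brute-force oracle (no shared expansion code with index/query)


def _naive_descendants(parents_of: dict, name: str) -> set[str]:
    children: dict[str, set[str]] = {}
    for n, rec in parents_of.items():
        for p in rec.parents:
            children.setdefault(p, set()).add(n)
    seen = {name}
    queue = deque([name])
    while queue:
        for child in children.get(queue.popleft(), ()):
            if child not in seen:
                seen.add(child)
                queue.append(child)
    return seen


def _naive_canonical(model: SemanticModel, pred: str) -> tuple[str, bool]:
    rec = model.predicates[pred]
    if rec.symmetric or rec.canonical or rec.inverse is None:
        return pred, False
    return rec.inverse, True


def _naive_subclass_reach(subclass_edges: list, start: str) -> set[str]:
    children: dict[str, set[str]] = {}
    for e in subclass_edges:
        children.setdefault(e.object, set()).add(e.subject)
    seen: set[str] = set()
    queue = deque([start])
    while queue:
        for child in children.get(queue.popleft(), ()):
            if child != start and child not in seen:
                seen.add(child)
                queue.append(child)
    return seen


def _naive_category_match(node: KnowledgeNode, wanted: list[str],
                          model: SemanticModel) -> bool:
    if not wanted:
        return True
    wanted_desc: set[str] = set()
    for qc in wanted:
        wanted_desc |= _naive_descendants(model.categories, strip_prefix(qc))
    for cat in node.categories:
        bare = strip_prefix(cat)
        if bare not in model.categories:
            bare = model.root_category
        if bare in wanted_desc:
            return True
    return False


def _naive_constraints(edge: KnowledgeEdge, constraints: list,
                       attribute_map: dict | None) -> bool:
    import re as _re
    type_to_prop = {
        (spec or {}).get("attribute_type_id"): prop
        for prop, spec in (attribute_map or {}).items()
    }
    for c in constraints:
        prop = type_to_prop.get(c.id, c.id)
        value = edge.properties.get(prop)
        if value is None:
            ok = False
        elif c.operator == "==":
            left = value if isinstance(value, list) else [value]
            right = c.value if isinstance(c.value, list) else [c.value]
            ok = any(r in left for r in right)
        elif c.operator == "matches":
            ok = _re.search(str(c.value), str(value)) is not None
        elif c.operator in (">", "<"):
            left_n, right_n = float(value), float(c.value)
            ok = left_n > right_n if c.operator == ">" else left_n < right_n
        else:
            ok = False
        if c.negated:
            ok = not ok
        if not ok:
            return False
    return True


def brute_force_answer(graph: Graph, model: SemanticModel,
                       subclass_edges: list, eqmap: EquivalenceMap,
                       qgraph: QueryGraph,
                       attribute_map: dict | None = None) -> set[tuple[str, str, str]]:
    """Answer a one-hop query by scanning every edge with naive expansion.

    Returns the set of ``(subject binding, object binding, edge id)`` triples,
    oriented by the query edge.  This is the correctness referee for the
    indexed engine; every reasoning rule is restated here from first
    principles rather than imported.
    """
    (qedge_key, qedge), = qgraph.qedges.items()
    subj_q = qgraph.qnodes[qedge.subject]
    obj_q = qgraph.qnodes[qedge.object]

    wanted = [strip_prefix(p) for p in (qedge.predicates or [model.root_predicate])]
    wanted_desc: set[str] = set()
    for qp in wanted:
        wanted_desc |= _naive_descendants(model.predicates, qp)

    desc_cache: dict[str, set[str]] = {}

    def pred_desc(name: str) -> set[str]:
        if name not in desc_cache:
            desc_cache[name] = _naive_descendants(model.predicates, name)
        return desc_cache[name]

    def resolution(ids: list[str]) -> set[str]:
        out: set[str] = set()
        for q in ids:
            rep = eqmap.cluster_of.get(q, q)
            members = eqmap.members_of.get(rep, {q})
            for m in members:
                out.add(m)
                out |= _naive_subclass_reach(subclass_edges, m)
        return {n for n in out if n in graph.nodes}

    subj_ids = resolution(subj_q.ids) if subj_q.ids else None
    obj_ids = resolution(obj_q.ids) if obj_q.ids else None

    def side_ok(node_id: str, pinned: set[str] | None, qnode) -> bool:
        if pinned is not None and node_id not in pinned:
            return False
        return _naive_category_match(graph.nodes[node_id], qnode.categories, model)

    triples: set[tuple[str, str, str]] = set()
    for edge in graph.edges.values():
        p_raw = strip_prefix(edge.predicate)
        if p_raw in model.predicates:
            ce, flipe = _naive_canonical(model, p_raw)
        else:
            ce, flipe = model.root_predicate, False
        se, oe = (edge.object, edge.subject) if flipe else (edge.subject, edge.object)
        symmetric = model.predicates[ce].symmetric

        match_fwd = match_rev = False
        for d in wanted_desc:
            cd, flipd = _naive_canonical(model, d)
            if ce not in pred_desc(cd):
                continue
            if symmetric or model.predicates[cd].symmetric:
                # a symmetric edge matches either way; a symmetric query
                # predicate matches either way
                match_fwd = match_rev = True
            elif flipd:
                match_rev = True
            else:
                match_fwd = True
            if match_fwd and match_rev:
                break
        if not (match_fwd or match_rev):
            continue
        if not _naive_constraints(edge, qedge.attribute_constraints, attribute_map):
            continue
        orientations = set()
        if match_fwd:
            orientations.add((se, oe))
        if match_rev:
            orientations.add((oe, se))
        for n0, n1 in orientations:
            if side_ok(n0, subj_ids, subj_q) and side_ok(n1, obj_ids, obj_q):
                triples.add((n0, n1, edge.id))
    return triples
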