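"""The in-memory adjacency index and subclass closure.

The engine's core data structure is a nested adjacency map::

    adj[node_id][neighbor_category][predicate][direction] -> {(neighbor_id, edge_id)}

All semantic reasoning that can be precomputed is baked in at build time so
query answering is plain dictionary lookup:

* **canonicity** -- every edge is stored under the canonical member of its
  predicate's inverse pair, with subject/object swapped (and the flip
  recorded) when the input predicate was the non-canonical direction;
* **hierarchy** -- each edge is registered under its canonical predicate
  *and every ancestor predicate*, and under every listed category of the
  neighbor *and every ancestor category*;
* **symmetry** -- symmetric-predicate edges are registered from both
  endpoints in direction ``out`` (no direction distinction exists for them).

This trades memory for constant-time lookup: queries pass their terms
verbatim with no descendant walk at query time.

The subclass closure maps each node to its transitive subclass descendants
(nodes connected by chains of ``subclass_of``-style edges), used to answer a
query pinned on a concept with that concept's subclasses.  Cycles terminate
and collapse: members of a cycle are descendants of each other but never of
themselves.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from collections import deque
from dataclasses import dataclass, field

from .canonicalize import EquivalenceMap
from .kgx import Graph, KnowledgeEdge, KnowledgeNode
from .semantic_model import SemanticModel, strip_prefix

__all__ = [
    "AdjacencyIndex",
    "SubclassIndex",
    "SnapshotError",
    "SnapshotNotFoundError",
    "SnapshotCorruptError",
    "SnapshotVersionError",
    "build_index",
    "lookup_neighbors",
    "build_subclass_closure",
    "save_index",
    "load_index",
    "SNAPSHOT_FORMAT_VERSION",
]

logger = logging.getLogger(__name__)

SNAPSHOT_FORMAT_VERSION = 1

OUT = "out"
IN = "in"


class SnapshotError(RuntimeError):
    """Base class for snapshot load failures."""


class SnapshotNotFoundError(SnapshotError):
    pass


class SnapshotCorruptError(SnapshotError):
    pass


class SnapshotVersionError(SnapshotError):
    pass


@dataclass
class AdjacencyIndex:
    #: node -> neighbor category -> predicate -> direction -> {(neighbor, edge_id)}
    adj: dict[str, dict[str, dict[str, dict[str, set[tuple[str, str]]]]]] = field(
        default_factory=dict)
    nodes_by_category: dict[str, set[str]] = field(default_factory=dict)
    edge_store: dict[str, KnowledgeEdge] = field(default_factory=dict)
    node_store: dict[str, KnowledgeNode] = field(default_factory=dict)
    #: edge ids whose stored orientation is flipped relative to the input file
    flipped_edges: set[str] = field(default_factory=set)
    build_meta: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edge_store)


@dataclass
class SubclassIndex:
    #: node -> transitive subclass descendants, exclusive of self
    descendants_of: dict[str, set[str]] = field(default_factory=dict)
    source: dict = field(default_factory=dict)

    def descendants(self, node_id: str) -> set[str]:
        return self.descendants_of.get(node_id, set())


def _register(index: AdjacencyIndex, node: str, category: str, predicate: str,
              direction: str, pair: tuple[str, str]) -> None:
    (index.adj.setdefault(node, {})
        .setdefault(category, {})
        .setdefault(predicate, {})
        .setdefault(direction, set())
        .add(pair))


def _node_category_keys(node: KnowledgeNode, model: SemanticModel) -> set[str]:
    """All categories listed on the node plus their ancestors."""
    keys: set[str] = set()
    for cat in node.categories:
        bare = strip_prefix(cat)
        if model.has_category(bare):
            keys |= model.category_ancestors(bare)
        else:
            keys.add(model.root_category)
    return keys


def build_index(graph: Graph, model: SemanticModel,
                options: dict | None = None) -> AdjacencyIndex:
    """Build the adjacency index with reasoning expansion baked in.

    Edges whose predicate is unknown to the model are indexed under the root
    predicate with a counted warning rather than rejected, so the build is
    total over imperfect inputs.  Deterministic for fixed inputs.
    """
    options = options or {}
    index = AdjacencyIndex(build_meta={
        "options": options,
        "graph_provenance": dict(graph.provenance),
        "unknown_predicate_edges": 0,
        "n_input_nodes": graph.n_nodes,
        "n_input_edges": graph.n_edges,
        "model_checksum": _model_checksum(model),
    })

    for nid in graph.nodes:
        node = graph.nodes[nid]
        index.node_store[nid] = node
        index.adj.setdefault(nid, {})
        for cat in _node_category_keys(node, model):
            index.nodes_by_category.setdefault(cat, set()).add(nid)

    for eid in graph.edges:
        edge = graph.edges[eid]
        raw_pred = strip_prefix(edge.predicate)
        if model.has_predicate(raw_pred):
            canonical, flipped = model.canonical_form(raw_pred)
        else:
            index.build_meta["unknown_predicate_edges"] += 1
            logger.warning("edge %s has model-unknown predicate %r; indexing under %r",
                           eid, raw_pred, model.root_predicate)
            canonical, flipped = model.root_predicate, False

        subject, object_ = (edge.object, edge.subject) if flipped else (edge.subject, edge.object)
        stored = KnowledgeEdge(id=eid, subject=subject, object=object_,
                               predicate=canonical, properties=edge.properties)
        index.edge_store[eid] = stored
        if flipped:
            index.flipped_edges.add(eid)

        pred_keys = model.predicate_ancestors(canonical)
        symmetric = model.is_symmetric(canonical)
        subj_cats = _node_category_keys(graph.nodes[subject], model)
        obj_cats = _node_category_keys(graph.nodes[object_], model)

        for pred in pred_keys:
            for cat in obj_cats:
                _register(index, subject, cat, pred, OUT, (object_, eid))
            if symmetric:
                for cat in subj_cats:
                    _register(index, object_, cat, pred, OUT, (subject, eid))
            else:
                for cat in subj_cats:
                    _register(index, object_, cat, pred, IN, (subject, eid))
    return index


def lookup_neighbors(index: AdjacencyIndex, node: str,
                     neighbor_categories: set[str] | None = None,
                     predicates: set[str] | None = None,
                     direction: str = "any") -> set[tuple[str, str]]:
    """Union of stored ``(neighbor, edge_id)`` pairs under the given keys.

    ``None`` means "all" for categories/predicates; an explicit empty set is
    a vacuous union.  Because expansion happened at build time, callers pass
    query terms verbatim.  Unknown nodes yield the empty set.
    """
    result: set[tuple[str, str]] = set()
    by_cat = index.adj.get(node)
    if not by_cat:
        return result
    directions = (OUT, IN) if direction == "any" else (direction,)
    cat_keys = by_cat.keys() if neighbor_categories is None else neighbor_categories
    for cat in cat_keys:
        by_pred = by_cat.get(cat)
        if not by_pred:
            continue
        pred_keys = by_pred.keys() if predicates is None else predicates
        for pred in pred_keys:
            by_dir = by_pred.get(pred)
            if not by_dir:
                continue
            for d in directions:
                result |= by_dir.get(d, set())
    return result


def build_subclass_closure(graph: Graph,
                           external_edges: list[KnowledgeEdge] | None = None,
                           subclass_predicates: set[str] | None = None,
                           max_depth: int | None = None) -> SubclassIndex:
    """Transitive closure of subclass relations, child-ward.

    An edge ``C -[subclass_of]-> B`` makes ``C`` a descendant of ``B``.
    ``descendants_of[x]`` holds every node reachable from ``x`` by one or
    more reversed subclass edges within *max_depth* (unbounded by default),
    excluding ``x`` itself even when a cycle makes it reachable.
    """
    subclass_predicates = {strip_prefix(p) for p in (subclass_predicates or {"subclass_of"})}
    children_of: dict[str, set[str]] = {}
    n_edges = 0
    cycles = 0
    all_edges = list(graph.edges.values()) + list(external_edges or [])
    for edge in all_edges:
        if strip_prefix(edge.predicate) in subclass_predicates:
            children_of.setdefault(edge.object, set()).add(edge.subject)
            n_edges += 1

    closure = SubclassIndex(source={
        "subclass_predicates": sorted(subclass_predicates),
        "n_subclass_edges": n_edges,
        "n_external_edges": len(external_edges or []),
        "max_depth": max_depth,
    })
    for root in children_of:
        seen: set[str] = set()
        queue: deque[tuple[str, int]] = deque([(root, 0)])
        while queue:
            current, depth = queue.popleft()
            if max_depth is not None and depth >= max_depth:
                continue
            for child in children_of.get(current, ()):
                if child == root:
                    cycles += 1
                    continue
                if child not in seen:
                    seen.add(child)
                    queue.append((child, depth + 1))
        if seen:
            closure.descendants_of[root] = seen
    if cycles:
        logger.warning("subclass closure encountered %d cycle edge(s); "
                       "self-membership suppressed", cycles)
        closure.source["cycle_edges"] = cycles
    return closure


# ---------------------------------------------------------------------------
# persistence


def _model_checksum(model: SemanticModel) -> str:
    payload = json.dumps({
        "categories": {n: sorted(c.parents) for n, c in model.categories.items()},
        "predicates": {
            n: [sorted(p.parents), p.symmetric, p.inverse or "", p.canonical]
            for n, p in model.predicates.items()
        },
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _node_to_json(n: KnowledgeNode) -> dict:
    return {"id": n.id, "name": n.name, "categories": n.categories,
            "equivalent_identifiers": n.equivalent_identifiers,
            "properties": n.properties}


def _edge_to_json(e: KnowledgeEdge) -> dict:
    return {"id": e.id, "subject": e.subject, "object": e.object,
            "predicate": e.predicate, "properties": e.properties}


def save_index(index: AdjacencyIndex, subclass: SubclassIndex,
               eqmap: EquivalenceMap, target: str) -> None:
    """Write a versioned snapshot directory (JSON files plus a manifest).

    Serialization is deterministic for fixed inputs: keys sorted, sets
    emitted as sorted lists.
    """
    os.makedirs(target, exist_ok=True)

    adj_json = {
        node: {
            cat: {
                pred: {d: sorted(map(list, pairs)) for d, pairs in by_dir.items()}
                for pred, by_dir in by_pred.items()
            }
            for cat, by_pred in by_cat.items()
        }
        for node, by_cat in index.adj.items()
    }
    payloads = {
        "adjacency.json": {
            "adj": adj_json,
            "nodes_by_category": {c: sorted(ids) for c, ids in index.nodes_by_category.items()},
            "flipped_edges": sorted(index.flipped_edges),
        },
        "nodes.json": {nid: _node_to_json(n) for nid, n in index.node_store.items()},
        "edges.json": {eid: _edge_to_json(e) for eid, e in index.edge_store.items()},
        "subclass.json": {
            "descendants_of": {k: sorted(v) for k, v in subclass.descendants_of.items()},
            "source": subclass.source,
        },
        "equivalence.json": {
            "cluster_of": eqmap.cluster_of,
            "members_of": {k: sorted(v) for k, v in eqmap.members_of.items()},
        },
    }
    checksums = {}
    for fname, payload in payloads.items():
        blob = json.dumps(payload, sort_keys=True).encode("utf-8")
        checksums[fname] = hashlib.sha256(blob).hexdigest()
        with open(os.path.join(target, fname), "wb") as fh:
            fh.write(blob)
    manifest = {
        "format_version": SNAPSHOT_FORMAT_VERSION,
        "build_meta": index.build_meta,
        "checksums": checksums,
    }
    with open(os.path.join(target, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)


def load_index(source: str) -> tuple[AdjacencyIndex, SubclassIndex, EquivalenceMap]:
    """Load a snapshot written by :func:`save_index`.

    Raises :class:`SnapshotNotFoundError` when the directory or manifest is
    missing, :class:`SnapshotVersionError` on a format-version mismatch, and
    :class:`SnapshotCorruptError` when a file fails its checksum or parse.
    """
    manifest_path = os.path.join(source, "manifest.json")
    if not os.path.isdir(source) or not os.path.exists(manifest_path):
        raise SnapshotNotFoundError(f"no snapshot at {source!r}")
    try:
        with open(manifest_path, "r", encoding="utf-8") as fh:
            manifest = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise SnapshotCorruptError(f"unreadable manifest in {source!r}: {exc}") from exc
    version = manifest.get("format_version")
    if version != SNAPSHOT_FORMAT_VERSION:
        raise SnapshotVersionError(
            f"snapshot format version {version!r} != supported {SNAPSHOT_FORMAT_VERSION}")

    blobs: dict[str, dict] = {}
    for fname, expected in manifest.get("checksums", {}).items():
        path = os.path.join(source, fname)
        try:
            with open(path, "rb") as fh:
                raw = fh.read()
        except OSError as exc:
            raise SnapshotCorruptError(f"missing snapshot file {fname!r}") from exc
        if hashlib.sha256(raw).hexdigest() != expected:
            raise SnapshotCorruptError(f"checksum mismatch for {fname!r}")
        try:
            blobs[fname] = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise SnapshotCorruptError(f"unparsable snapshot file {fname!r}") from exc

    try:
        adjacency = blobs["adjacency.json"]
        index = AdjacencyIndex(build_meta=manifest.get("build_meta", {}))
        index.adj = {
            node: {
                cat: {
                    pred: {d: {tuple(p) for p in pairs} for d, pairs in by_dir.items()}
                    for pred, by_dir in by_pred.items()
                }
                for cat, by_pred in by_cat.items()
            }
            for node, by_cat in adjacency["adj"].items()
        }
        index.nodes_by_category = {c: set(ids) for c, ids in adjacency["nodes_by_category"].items()}
        index.flipped_edges = set(adjacency["flipped_edges"])
        index.node_store = {
            nid: KnowledgeNode(**rec) for nid, rec in blobs["nodes.json"].items()}
        index.edge_store = {
            eid: KnowledgeEdge(**rec) for eid, rec in blobs["edges.json"].items()}
        sub = blobs["subclass.json"]
        subclass = SubclassIndex(
            descendants_of={k: set(v) for k, v in sub["descendants_of"].items()},
            source=sub["source"])
        eq = blobs["equivalence.json"]
        eqmap = EquivalenceMap(
            cluster_of=dict(eq["cluster_of"]),
            members_of={k: set(v) for k, v in eq["members_of"].items()})
    except (KeyError, TypeError) as exc:
        raise SnapshotCorruptError(f"snapshot structure invalid: {exc}") from exc
    return index, subclass, eqmap
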