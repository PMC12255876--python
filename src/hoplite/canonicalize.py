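"""Concept equivalence and graph canonicalization.

Different CURIEs frequently name the same real-world concept
(``CHEBI:15365`` and ``DRUGBANK:DB00316`` are both acetaminophen).  This
module groups CURIEs into equivalence clusters -- from each node's
``equivalent_identifiers`` property, or from a pluggable resolver honoring
the Node-Normalizer-style contract -- and optionally rewrites the graph to
one node per cluster with edges re-pointed to cluster representatives.

Clustering is union-find with path compression over sorted node ids, so
representatives are reproducible run to run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

from .kgx import Graph, KnowledgeEdge, KnowledgeNode

__all__ = [
    "EquivalenceMap",
    "Resolver",
    "FileResolver",
    "build_equivalence_map",
    "choose_preferred_id",
    "canonicalize_graph",
]

logger = logging.getLogger(__name__)

#: Resolver contract: batch of CURIEs -> {curie: {"members": [...], "preferred": curie}}.
#: Must return an entry (possibly a singleton) for every queried CURIE.
Resolver = Callable[[list[str]], dict[str, dict]]


class FileResolver:
    """Offline resolver backed by a JSON table ``{curie: {members, preferred}}``.

    Stands in for a live normalization service so builds work without
    network access; any callable honoring the same contract can replace it.
    """

    def __init__(self, path: str):
        with open(path, "r", encoding="utf-8") as fh:
            self._table: dict[str, dict] = json.load(fh)

    def __call__(self, curies: list[str]) -> dict[str, dict]:
        return {
            c: self._table.get(c, {"members": [c], "preferred": c})
            for c in curies
        }


@dataclass
class EquivalenceMap:
    """Partition of known CURIEs into clusters with preferred representatives."""

    cluster_of: dict[str, str] = field(default_factory=dict)
    members_of: dict[str, set[str]] = field(default_factory=dict)

    def representative(self, curie: str) -> str:
        return self.cluster_of.get(curie, curie)

    def members(self, curie: str) -> set[str]:
        """All CURIEs in *curie*'s cluster (singleton if unknown)."""
        return self.members_of.get(self.representative(curie), {curie})


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        root = x
        while self.parent.setdefault(root, root) != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def choose_preferred_id(members: Iterable[str],
                        prefix_priority: list[str] | None = None) -> str:
    """Pick the cluster representative.

    The member whose CURIE prefix ranks earliest in *prefix_priority* wins;
    ties and unlisted prefixes fall back to lexicographic order on the full
    CURIE string (textual, not numeric: ``X:10`` sorts before ``X:2``).
    """
    prefix_priority = prefix_priority or []
    rank = {p: i for i, p in enumerate(prefix_priority)}

    def key(curie: str) -> tuple[int, str]:
        prefix = curie.split(":", 1)[0]
        return rank.get(prefix, len(prefix_priority)), curie

    return min(members, key=key)


def build_equivalence_map(graph: Graph, resolver: Resolver | None = None,
                          prefix_priority: list[str] | None = None) -> EquivalenceMap:
    """Union each node's ``{id} ∪ equivalent_identifiers`` into clusters.

    For nodes that list no equivalents, *resolver* (if given) supplies cluster
    members; a resolver failure degrades to singleton clusters with a warning
    so builds stay possible offline.  Representatives are chosen by
    :func:`choose_preferred_id`.
    """
    uf = _UnionFind()
    node_ids = sorted(graph.nodes)
    unresolved: list[str] = []
    for nid in node_ids:
        node = graph.nodes[nid]
        uf.find(nid)
        if node.equivalent_identifiers:
            for eq in node.equivalent_identifiers:
                uf.union(nid, eq)
        elif resolver is not None:
            unresolved.append(nid)

    if unresolved:
        try:
            answers = resolver(unresolved)
            for nid in unresolved:
                for member in answers.get(nid, {}).get("members", [nid]):
                    uf.union(nid, member)
        except Exception as exc:  # resolver is external: degrade, don't die
            logger.warning("resolver failed (%s); falling back to singleton clusters", exc)

    clusters: dict[str, set[str]] = {}
    for curie in sorted(uf.parent):
        clusters.setdefault(uf.find(curie), set()).add(curie)

    eqmap = EquivalenceMap()
    for members in clusters.values():
        rep = choose_preferred_id(members, prefix_priority)
        eqmap.members_of[rep] = members
        for m in members:
            eqmap.cluster_of[m] = rep
    return eqmap


def _dedup_key(edge: KnowledgeEdge) -> tuple:
    return (edge.subject, edge.object, edge.predicate,
            str(edge.properties.get("primary_knowledge_source", "")))


def _merge_properties(target: dict, incoming: Mapping) -> None:
    for k, v in incoming.items():
        if k not in target:
            target[k] = v
        elif isinstance(target[k], list) or isinstance(v, list):
            existing = target[k] if isinstance(target[k], list) else [target[k]]
            new = v if isinstance(v, list) else [v]
            merged = list(existing)
            for item in new:
                if item not in merged:
                    merged.append(item)
            target[k] = merged
        elif target[k] != v:
            stash = target.setdefault("_merged_values", {})
            stash.setdefault(k, [])
            if v not in stash[k]:
                stash[k].append(v)


def canonicalize_graph(graph: Graph, eqmap: EquivalenceMap) -> Graph:
    """Merge equivalent nodes: one node per cluster, edges re-pointed.

    Merged nodes take the representative CURIE as id, the union of member
    categories (first-seen order), the representative member's name when it
    is a graph node, and all cluster members as ``equivalent_identifiers``.
    Re-pointed edges that become duplicates under
    ``(subject, object, predicate, primary_knowledge_source)`` are merged
    with list properties concatenated and deduplicated; self-loops created by
    merging are kept.  The operation is idempotent.
    """
    out = Graph(provenance=dict(graph.provenance))
    out.provenance["canonicalized"] = True

    for nid in graph.nodes:
        node = graph.nodes[nid]
        rep = eqmap.representative(nid)
        members = sorted(eqmap.members(nid))
        if rep not in out.nodes:
            out.nodes[rep] = KnowledgeNode(
                id=rep, name="", categories=[],
                equivalent_identifiers=members if len(members) > 1 else [],
                properties={})
        merged = out.nodes[rep]
        for cat in node.categories:
            if cat not in merged.categories:
                merged.categories.append(cat)
        if nid == rep or not merged.name:
            # representative's own name wins; otherwise first contributor
            if nid == rep:
                merged.name = node.name
            elif not merged.name:
                merged.name = node.name
        if nid == rep:
            rep_props = dict(node.properties)
            _merge_properties(rep_props, merged.properties)
            merged.properties = rep_props
        else:
            _merge_properties(merged.properties, node.properties)

    seen: dict[tuple, str] = {}
    for eid in graph.edges:
        edge = graph.edges[eid]
        repointed = KnowledgeEdge(
            id=edge.id,
            subject=eqmap.representative(edge.subject),
            object=eqmap.representative(edge.object),
            predicate=edge.predicate,
            properties={k: (list(v) if isinstance(v, list) else v)
                        for k, v in edge.properties.items()},
        )
        key = _dedup_key(repointed)
        if key in seen:
            _merge_properties(out.edges[seen[key]].properties, repointed.properties)
        else:
            seen[key] = repointed.id
            out.edges[repointed.id] = repointed
    return out
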