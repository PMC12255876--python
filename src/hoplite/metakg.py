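"""Meta knowledge graph and test triples.

The meta knowledge graph is the schema-level summary of a served graph:
which (subject category, predicate, object category) combinations it
contains and how often, plus the CURIE prefixes observed per category.
Test triples pick one concrete exemplar edge per meta-edge so an external
harness can smoke-test the live API.

Both are computed from the *stored canonical* edges (one entry per input
edge, no hierarchy expansion) so counts reflect the graph, not the
reasoning fan-out, and from each node's most specific category -- by KGX
convention the first entry of its category list.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from .index import AdjacencyIndex
from .semantic_model import SemanticModel, add_prefix, strip_prefix

__all__ = ["MetaKG", "TestTriples", "build_meta_kg", "build_test_triples"]


@dataclass
class MetaKG:
    #: category -> {"id_prefixes": [...]} (most-frequent prefix first)
    meta_nodes: dict[str, dict] = field(default_factory=dict)
    #: unique (subject_category, predicate, object_category) with edge counts
    meta_edges: list[dict] = field(default_factory=list)
    #: category-assignment policy used to build the meta-edges
    all_categories: bool = False

    def to_trapi(self) -> dict:
        return {
            "nodes": {
                add_prefix(cat): {"id_prefixes": rec["id_prefixes"]}
                for cat, rec in sorted(self.meta_nodes.items())
            },
            "edges": [
                {
                    "subject": add_prefix(e["subject_category"]),
                    "predicate": add_prefix(e["predicate"]),
                    "object": add_prefix(e["object_category"]),
                    "count": e["count"],
                }
                for e in self.meta_edges
            ],
        }


@dataclass
class TestTriples:
    triples: list[dict] = field(default_factory=list)

    def to_json(self) -> list[dict]:
        return [
            {
                "subject_category": add_prefix(t["subject_category"]),
                "predicate": add_prefix(t["predicate"]),
                "object_category": add_prefix(t["object_category"]),
                "subject_id": t["subject_id"],
                "object_id": t["object_id"],
            }
            for t in self.triples
        ]


def _most_specific_category(index: AdjacencyIndex, node_id: str,
                            model: SemanticModel) -> str:
    cats = index.node_store[node_id].categories
    if not cats:
        return model.root_category
    first = strip_prefix(cats[0])
    return first if model.has_category(first) else model.root_category


def build_meta_kg(index: AdjacencyIndex, model: SemanticModel,
                  all_categories: bool = False) -> MetaKG:
    """Aggregate stored edges into meta-edges with counts.

    With ``all_categories=False`` (default) each edge contributes exactly one
    meta-edge, keyed by the endpoints' most specific categories, so counts sum
    to the stored edge count.  With ``all_categories=True`` every listed
    category pair contributes, which inflates the sum accordingly.
    """
    counts: dict[tuple[str, str, str], int] = {}
    for eid in sorted(index.edge_store):
        edge = index.edge_store[eid]
        if all_categories:
            subj_cats = [strip_prefix(c) for c in index.node_store[edge.subject].categories]
            obj_cats = [strip_prefix(c) for c in index.node_store[edge.object].categories]
        else:
            subj_cats = [_most_specific_category(index, edge.subject, model)]
            obj_cats = [_most_specific_category(index, edge.object, model)]
        for sc in subj_cats:
            for oc in obj_cats:
                key = (sc, edge.predicate, oc)
                counts[key] = counts.get(key, 0) + 1

    # observed CURIE prefixes per most-specific category, frequency then name
    prefix_counts: dict[str, dict[str, int]] = {}
    for nid in index.node_store:
        cat = _most_specific_category(index, nid, model)
        prefix = nid.split(":", 1)[0]
        prefix_counts.setdefault(cat, {})
        prefix_counts[cat][prefix] = prefix_counts[cat].get(prefix, 0) + 1

    metakg = MetaKG(all_categories=all_categories)
    used_categories = ({sc for sc, _, _ in counts} | {oc for _, _, oc in counts}
                       | set(prefix_counts))
    for cat in sorted(used_categories):
        observed = prefix_counts.get(cat, {})
        ordered = sorted(observed, key=lambda p: (-observed[p], p))
        declared = model.category_prefixes.get(cat, [])
        metakg.meta_nodes[cat] = {
            "id_prefixes": ordered or list(declared)}
    metakg.meta_edges = [
        {"subject_category": sc, "predicate": pred, "object_category": oc,
         "count": n}
        for (sc, pred, oc), n in sorted(counts.items())
    ]
    return metakg


def build_test_triples(index: AdjacencyIndex, metakg: MetaKG,
                       seed: int = 0, model: SemanticModel | None = None) -> TestTriples:
    """Select one exemplar stored edge per meta-edge, deterministically.

    The exemplar is the edge whose seed-keyed hash orders smallest, so a
    fixed seed gives byte-identical output across runs while different seeds
    sample different exemplars.  *model* is used to re-derive most-specific
    categories exactly as ``build_meta_kg`` did; without it, the first listed
    category is taken verbatim.
    """
    def order_key(eid: str) -> str:
        return hashlib.sha256(f"{seed}:{eid}".encode()).hexdigest()

    def specific(node_id: str) -> str:
        if model is not None:
            return _most_specific_category(index, node_id, model)
        cats = index.node_store[node_id].categories
        return strip_prefix(cats[0]) if cats else ""

    best: dict[tuple[str, str, str], str] = {}
    for eid in sorted(index.edge_store):
        edge = index.edge_store[eid]
        if metakg.all_categories:
            subj_cats = [strip_prefix(c) for c in index.node_store[edge.subject].categories]
            obj_cats = [strip_prefix(c) for c in index.node_store[edge.object].categories]
        else:
            subj_cats = [specific(edge.subject)]
            obj_cats = [specific(edge.object)]
        for sc in subj_cats:
            for oc in obj_cats:
                key = (sc, edge.predicate, oc)
                if key not in best or order_key(eid) < order_key(best[key]):
                    best[key] = eid

    triples = TestTriples()
    for meta_edge in metakg.meta_edges:
        key = (meta_edge["subject_category"], meta_edge["predicate"],
               meta_edge["object_category"])
        eid = best.get(key)
        if eid is None:
            continue
        edge = index.edge_store[eid]
        triples.triples.append({
            "subject_category": key[0],
            "predicate": key[1],
            "object_category": key[2],
            "subject_id": edge.subject,
            "object_id": edge.object,
        })
    return triples
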