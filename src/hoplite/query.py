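"""One-hop TRAPI-shaped query answering over the adjacency index.

A query graph is two query nodes joined by one query edge.  Nodes may be
constrained by concrete identifiers (``ids``) and semantic types
(``categories``); the edge by ``predicates`` and ``attribute_constraints``.
At least one query node must be pinned to identifiers.

Answering applies five reasoning expansions, all precomputed into the index
at build time: predicate/category hierarchy descent, predicate symmetry,
canonical-direction flipping, concept-equivalence resolution, and transitive
subclass chaining of pinned concepts.  Answers reached through equivalence
or subclass reasoning carry a ``query_id`` on their node binding naming the
CURIE the client actually asked about.

Output is deterministic: results sorted by (subject binding, object
binding), knowledge-graph keys sorted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any

from .canonicalize import EquivalenceMap
from .index import IN, OUT, AdjacencyIndex, SubclassIndex, lookup_neighbors
from .kgx import KnowledgeEdge
from .semantic_model import SemanticModel, add_prefix, strip_prefix

__all__ = [
    "QNode",
    "QEdge",
    "AttributeConstraint",
    "QueryGraph",
    "ConstraintEvaluationError",
    "InvalidQueryError",
    "parse_query_graph",
    "validate_query",
    "resolve_pinned_ids",
    "apply_attribute_constraints",
    "answer_query",
    "result_triples",
]

_OPERATORS = {"==", ">", "<", "matches"}


class InvalidQueryError(ValueError):
    """Raised when answering is attempted on a query that failed validation."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


class ConstraintEvaluationError(ValueError):
    """An attribute constraint cannot be evaluated (e.g. non-numeric > operand)."""


@dataclass
class AttributeConstraint:
    id: str
    operator: str
    value: Any
    negated: bool = False


@dataclass
class QNode:
    ids: list[str] = field(default_factory=list)
    categories: list[str] = field(default_factory=list)

    @property
    def pinned(self) -> bool:
        return bool(self.ids)


@dataclass
class QEdge:
    subject: str
    object: str
    predicates: list[str] = field(default_factory=list)
    attribute_constraints: list[AttributeConstraint] = field(default_factory=list)


@dataclass
class QueryGraph:
    qnodes: dict[str, QNode]
    qedges: dict[str, QEdge]


def parse_query_graph(body: dict) -> QueryGraph:
    """Parse a TRAPI request body (or bare query_graph dict) into a QueryGraph."""
    qg = body
    if "message" in qg:
        qg = qg["message"]
    if "query_graph" in qg:
        qg = qg["query_graph"]
    qnodes = {}
    for key, raw in (qg.get("nodes") or {}).items():
        raw = raw or {}
        qnodes[key] = QNode(
            ids=list(raw.get("ids") or []),
            categories=list(raw.get("categories") or []),
        )
    qedges = {}
    for key, raw in (qg.get("edges") or {}).items():
        raw = raw or {}
        constraints = [
            AttributeConstraint(
                id=c.get("id", ""),
                operator=c.get("operator", "=="),
                value=c.get("value"),
                negated=bool(c.get("not", c.get("negated", False))),
            )
            for c in (raw.get("attribute_constraints") or [])
        ]
        qedges[key] = QEdge(
            subject=raw.get("subject", ""),
            object=raw.get("object", ""),
            predicates=list(raw.get("predicates") or []),
            attribute_constraints=constraints,
        )
    return QueryGraph(qnodes=qnodes, qedges=qedges)


def validate_query(qgraph: QueryGraph, model: SemanticModel) -> list[str]:
    """Return the list of reasons the query cannot be answered (empty = OK)."""
    errors: list[str] = []
    if len(qgraph.qnodes) != 2 or len(qgraph.qedges) != 1:
        errors.append(
            f"not one-hop: expected exactly 2 query nodes and 1 query edge, "
            f"got {len(qgraph.qnodes)} node(s) and {len(qgraph.qedges)} edge(s)")
        return errors
    qedge = next(iter(qgraph.qedges.values()))
    if {qedge.subject, qedge.object} != set(qgraph.qnodes):
        errors.append("query edge subject/object must name the two query nodes")
    if not any(q.pinned for q in qgraph.qnodes.values()):
        errors.append("at least one query node must be pinned to ids")
    for key, qnode in qgraph.qnodes.items():
        for cat in qnode.categories:
            if not model.has_category(cat):
                errors.append(f"query node {key!r}: unknown category {cat!r}")
    for pred in qedge.predicates:
        if not model.has_predicate(pred):
            errors.append(f"query edge: unknown predicate {pred!r}")
    for c in qedge.attribute_constraints:
        if c.operator not in _OPERATORS:
            errors.append(f"query edge: unknown constraint operator {c.operator!r}")
        if not c.id:
            errors.append("query edge: attribute constraint missing id")
    return errors


def resolve_pinned_ids(ids: list[str], eqmap: EquivalenceMap,
                       subclass: SubclassIndex,
                       index: AdjacencyIndex) -> dict[str, str]:
    """Map each queried CURIE to the concrete graph nodes that answer for it.

    For a queried CURIE ``q``, the candidates are every member of ``q``'s
    equivalence cluster plus the transitive subclass descendants of each
    member; candidates absent from the index resolve to nothing.  The
    returned map goes concrete node id -> original queried CURIE
    (``query_id``); when several queried CURIEs reach the same concrete node,
    the first in the query's id order wins.
    """
    resolved: dict[str, str] = {}
    for q in ids:
        candidates: set[str] = set()
        for member in eqmap.members(q):
            candidates.add(member)
            candidates |= subclass.descendants(member)
        for concrete in sorted(candidates):
            if concrete in index.node_store and concrete not in resolved:
                resolved[concrete] = q
    return resolved


def _constraint_matches(edge_value: Any, operator: str, value: Any,
                        constraint_id: str) -> bool:
    if operator == "==":
        left = edge_value if isinstance(edge_value, list) else [edge_value]
        right = value if isinstance(value, list) else [value]
        return any(item in left for item in right)
    if operator == "matches":
        return re.search(str(value), str(edge_value)) is not None
    # numeric comparison
    try:
        left_num = float(edge_value)
        right_num = float(value)
    except (TypeError, ValueError) as exc:
        raise ConstraintEvaluationError(
            f"constraint {constraint_id!r}: operator {operator!r} requires numeric "
            f"operands, got {edge_value!r} and {value!r}") from exc
    return left_num > right_num if operator == ">" else left_num < right_num


def apply_attribute_constraints(edge: KnowledgeEdge,
                                constraints: list[AttributeConstraint],
                                attribute_map: dict[str, dict] | None = None) -> bool:
    """Conjunction of attribute constraints against the edge's properties.

    Each constraint id is translated to an edge property name through
    *attribute_map* (``{property: {attribute_type_id: ...}}``), falling back
    to the raw id.  A missing property leaves the constraint unsatisfied
    before negation; ``negated`` inverts the single constraint's outcome.
    """
    attribute_map = attribute_map or {}
    type_to_property = {
        spec.get("attribute_type_id"): prop for prop, spec in attribute_map.items()
    }
    for c in constraints:
        prop = type_to_property.get(c.id, c.id)
        if prop in edge.properties:
            satisfied = _constraint_matches(edge.properties[prop], c.operator,
                                            c.value, c.id)
        else:
            satisfied = False
        if c.negated:
            satisfied = not satisfied
        if not satisfied:
            return False
    return True


# ---------------------------------------------------------------------------
# answering


def _serialize_node(node, model: SemanticModel,
                    attribute_map: dict[str, dict] | None) -> dict:
    attrs = _serialize_attributes(node.properties, attribute_map, exclude=())
    out: dict[str, Any] = {
        "name": node.name,
        "categories": [add_prefix(strip_prefix(c)) for c in node.categories],
        "attributes": attrs,
    }
    if node.equivalent_identifiers:
        out["attributes"] = attrs + [{
            "attribute_type_id": "biolink:xref",
            "value": list(node.equivalent_identifiers),
        }]
    return out


def _serialize_attributes(properties: dict, attribute_map: dict[str, dict] | None,
                          exclude: tuple = ("primary_knowledge_source",)) -> list[dict]:
    attribute_map = attribute_map or {}
    attrs = []
    for prop in sorted(properties):
        if prop in exclude or prop.startswith("_"):
            continue
        spec = attribute_map.get(prop, {})
        attr = {
            "attribute_type_id": spec.get("attribute_type_id", prop),
            "value": properties[prop],
        }
        if "value_type" in spec:
            attr["value_type_id"] = spec["value_type"]
        attrs.append(attr)
    return attrs


def _serialize_edge(edge: KnowledgeEdge, model: SemanticModel,
                    attribute_map: dict[str, dict] | None) -> dict:
    out: dict[str, Any] = {
        "subject": edge.subject,
        "predicate": add_prefix(edge.predicate),
        "object": edge.object,
        "attributes": _serialize_attributes(edge.properties, attribute_map),
    }
    primary = edge.properties.get("primary_knowledge_source")
    sources = []
    if primary:
        if isinstance(primary, list):
            primary = primary[0]
        sources.append({"resource_id": primary,
                        "resource_role": "primary_knowledge_source"})
    out["sources"] = sources
    return out


def _expand_predicates(predicates: list[str],
                       model: SemanticModel) -> list[tuple[str, bool]]:
    """Expand query predicates to (canonical predicate, flipped) lookup pairs."""
    wanted = predicates or [model.root_predicate]
    pairs: set[tuple[str, bool]] = set()
    for qp in wanted:
        for desc in model.predicate_descendants(strip_prefix(qp)):
            pairs.add(model.canonical_form(desc))
    return sorted(pairs)


def _expand_categories(categories: list[str],
                       model: SemanticModel) -> set[str] | None:
    if not categories:
        return None
    expanded: set[str] = set()
    for cat in categories:
        expanded |= model.category_descendants(strip_prefix(cat))
    return expanded


def answer_query(qgraph: QueryGraph, index: AdjacencyIndex, model: SemanticModel,
                 subclass: SubclassIndex, eqmap: EquivalenceMap,
                 attribute_map: dict[str, dict] | None = None) -> dict:
    """Answer a validated one-hop query; returns a TRAPI-shaped response dict.

    Matching triples are gathered from the pinned side (the side with fewer
    resolved concrete ids when both are pinned; ties go to the query-edge
    subject) via constant-time index lookups, then filtered by attribute
    constraints and, when the opposite side is pinned too, by its resolved
    id set.
    """
    errors = validate_query(qgraph, model)
    if errors:
        raise InvalidQueryError(errors)

    (qedge_key, qedge), = qgraph.qedges.items()
    subj_key, obj_key = qedge.subject, qedge.object

    resolutions: dict[str, dict[str, str]] = {}
    for key in (subj_key, obj_key):
        if qgraph.qnodes[key].pinned:
            resolutions[key] = resolve_pinned_ids(
                qgraph.qnodes[key].ids, eqmap, subclass, index)

    if len(resolutions) == 2:
        # start from the sparser side; tie goes to the query-edge subject
        pinned_key = min((subj_key, obj_key),
                         key=lambda k: (len(resolutions[k]), k != subj_key))
    else:
        (pinned_key,) = resolutions
    other_key = obj_key if pinned_key == subj_key else subj_key
    pinned_is_subject = pinned_key == subj_key

    pred_pairs = _expand_predicates(qedge.predicates, model)
    other_cats = _expand_categories(qgraph.qnodes[other_key].categories, model)
    other_resolution = resolutions.get(other_key)

    # a pinned qnode's categories still constrain its own bindings
    pinned_cats = _expand_categories(qgraph.qnodes[pinned_key].categories, model)
    pinned_concretes = [
        c for c in resolutions[pinned_key]
        if pinned_cats is None
        or any(c in index.nodes_by_category.get(cat, ()) for cat in pinned_cats)
    ]

    # (subject_binding, object_binding) -> sorted edge ids
    matches: dict[tuple[str, str], set[str]] = {}
    for concrete in pinned_concretes:
        for canonical_pred, flipped in pred_pairs:
            if model.is_symmetric(canonical_pred):
                # direction carries no meaning for a symmetric query predicate:
                # directional descendant edges match in both orientations
                candidates = lookup_neighbors(
                    index, concrete, other_cats, {canonical_pred}, "any")
            else:
                direction = OUT if (pinned_is_subject != flipped) else IN
                candidates = lookup_neighbors(
                    index, concrete, other_cats, {canonical_pred}, direction)
                if direction == IN:
                    # symmetric stored edges live only in `out`, yet match a
                    # flipped query predicate in either orientation
                    candidates |= {
                        (neighbor, eid) for neighbor, eid in lookup_neighbors(
                            index, concrete, other_cats, {canonical_pred}, OUT)
                        if model.is_symmetric(index.edge_store[eid].predicate)
                    }
            for neighbor, eid in candidates:
                edge = index.edge_store[eid]
                if other_resolution is not None and neighbor not in other_resolution:
                    continue
                if not apply_attribute_constraints(
                        edge, qedge.attribute_constraints, attribute_map):
                    continue
                pair = (concrete, neighbor) if pinned_is_subject else (neighbor, concrete)
                matches.setdefault(pair, set()).add(eid)

    # assemble response
    kg_nodes: dict[str, dict] = {}
    kg_edges: dict[str, dict] = {}
    results = []
    for (subj_id, obj_id) in sorted(matches):
        edge_ids = sorted(matches[(subj_id, obj_id)])
        for nid in (subj_id, obj_id):
            if nid not in kg_nodes:
                kg_nodes[nid] = _serialize_node(index.node_store[nid], model,
                                                attribute_map)
        for eid in edge_ids:
            if eid not in kg_edges:
                kg_edges[eid] = _serialize_edge(index.edge_store[eid], model,
                                                attribute_map)
        node_bindings = {}
        for key, bound in ((subj_key, subj_id), (obj_key, obj_id)):
            binding: dict[str, Any] = {"id": bound}
            resolution = resolutions.get(key)
            if resolution is not None:
                query_id = resolution.get(bound)
                if query_id is not None and query_id != bound:
                    binding["query_id"] = query_id
            node_bindings[key] = [binding]
        results.append({
            "node_bindings": node_bindings,
            "analyses": [{
                "edge_bindings": {qedge_key: [{"id": eid} for eid in edge_ids]},
            }],
        })

    return {
        "message": {
            "query_graph": _echo_query_graph(qgraph),
            "knowledge_graph": {
                "nodes": {k: kg_nodes[k] for k in sorted(kg_nodes)},
                "edges": {k: kg_edges[k] for k in sorted(kg_edges)},
            },
            "results": results,
        },
        "status": "Success",
        "description": f"{len(results)} result(s), {len(kg_edges)} edge(s)",
    }


def _echo_query_graph(qgraph: QueryGraph) -> dict:
    nodes = {}
    for key, q in qgraph.qnodes.items():
        rec: dict[str, Any] = {}
        if q.ids:
            rec["ids"] = list(q.ids)
        if q.categories:
            rec["categories"] = [add_prefix(strip_prefix(c)) for c in q.categories]
        nodes[key] = rec
    edges = {}
    for key, e in qgraph.qedges.items():
        rec = {"subject": e.subject, "object": e.object}
        if e.predicates:
            rec["predicates"] = [add_prefix(strip_prefix(p)) for p in e.predicates]
        if e.attribute_constraints:
            rec["attribute_constraints"] = [
                {"id": c.id, "operator": c.operator, "value": c.value, "not": c.negated}
                for c in e.attribute_constraints
            ]
        edges[key] = rec
    return {"nodes": nodes, "edges": edges}


def result_triples(response: dict, qedge_key: str | None = None) -> set[tuple[str, str, str]]:
    """Extract the (subject id, object id, edge id) triple set from a response.

    Triples are oriented by the query edge: the first element binds the query
    edge's subject node.  This is the comparison form used against the
    brute-force oracle.
    """
    message = response.get("message", response)
    qg = message["query_graph"]
    if qedge_key is None:
        (qedge_key,) = qg["edges"]
    subj_key = qg["edges"][qedge_key]["subject"]
    obj_key = qg["edges"][qedge_key]["object"]
    triples = set()
    for result in message["results"]:
        subj = result["node_bindings"][subj_key][0]["id"]
        obj = result["node_bindings"][obj_key][0]["id"]
        for analysis in result["analyses"]:
            for binding in analysis["edge_bindings"][qedge_key]:
                triples.add((subj, obj, binding["id"]))
    return triples
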