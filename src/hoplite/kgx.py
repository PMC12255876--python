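"""Read and write knowledge graphs in the two flat-file KGX dialects.

KGX (Knowledge Graph Exchange) serializes a graph as separate nodes and edges
files, either tab-separated with a header row or JSON Lines (one object per
line).  Multi-valued fields (``category``, ``publications``, ...) are native
arrays in JSON Lines and delimiter-joined strings (``|`` by default) in TSV.

``read_graph`` is deliberately forgiving about real-world exports: edges whose
endpoints are missing from the nodes file are dropped with a counted warning,
duplicate node ids are last-wins, duplicate edge ids are deterministically
re-suffixed, and nodes without a category get a configurable default (the
semantic model's root category in the service pipeline).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from typing import Any, Iterator

__all__ = [
    "KnowledgeNode",
    "KnowledgeEdge",
    "Graph",
    "FormatError",
    "read_graph",
    "write_graph",
    "parse_list_field",
]

logger = logging.getLogger(__name__)

DEFAULT_LIST_DELIMITER = "|"

#: node columns that are structured fields, not free-form properties
_NODE_CORE = {"id", "name", "category", "categories"}
_EDGE_CORE = {"id", "subject", "object", "predicate"}

#: properties conventionally list-valued in KGX TSV exports
_LIST_PROPERTIES = {
    "category",
    "categories",
    "equivalent_identifiers",
    "publications",
    "provided_by",
    "knowledge_source",
    "aggregator_knowledge_source",
    "xref",
    "synonym",
}


class FormatError(ValueError):
    """A source file does not conform to the KGX dialect it claims."""


@dataclass
class KnowledgeNode:
    id: str
    name: str = ""
    categories: list[str] = field(default_factory=list)
    equivalent_identifiers: list[str] = field(default_factory=list)
    properties: dict[str, Any] = field(default_factory=dict)

    def prefix(self) -> str:
        return self.id.split(":", 1)[0]


@dataclass
class KnowledgeEdge:
    id: str
    subject: str
    object: str
    predicate: str
    properties: dict[str, Any] = field(default_factory=dict)


@dataclass
class Graph:
    nodes: dict[str, KnowledgeNode] = field(default_factory=dict)
    edges: dict[str, KnowledgeEdge] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def equal_content(self, other: "Graph") -> bool:
        """Structural equality on nodes and edges, ignoring provenance."""
        return _node_repr(self) == _node_repr(other) and _edge_repr(self) == _edge_repr(other)


def _node_repr(g: Graph) -> dict:
    return {
        nid: (n.name, tuple(n.categories), tuple(n.equivalent_identifiers),
              json.dumps(n.properties, sort_keys=True))
        for nid, n in g.nodes.items()
    }


def _edge_repr(g: Graph) -> dict:
    return {
        eid: (e.subject, e.object, e.predicate, json.dumps(e.properties, sort_keys=True))
        for eid, e in g.edges.items()
    }


def parse_list_field(raw: Any, dialect: str = "tsv",
                     delimiter: str = DEFAULT_LIST_DELIMITER) -> list:
    """Parse a possibly multi-valued field into a list.

    JSON Lines passes native arrays through; TSV splits on *delimiter*,
    strips surrounding whitespace and drops empty items.
    """
    if raw is None:
        return []
    if dialect == "jsonlines":
        if isinstance(raw, list):
            return raw
        return [raw] if raw != "" else []
    text = str(raw)
    if not text.strip():
        return []
    items = [item.strip() for item in text.split(delimiter)]
    return [item for item in items if item]


def synthesize_edge_id(subject: str, predicate: str, object_: str,
                       primary_source: str = "") -> str:
    """Deterministic edge id for rows that lack one."""
    key = f"{subject}|{predicate}|{object_}|{primary_source}"
    return "e" + hashlib.sha1(key.encode("utf-8")).hexdigest()[:16]


# ---------------------------------------------------------------------------
# reading


def _fetch(source: str, cache_dir: str | None) -> str:
    """Return a local path for *source*, downloading URLs into a cache."""
    parsed = urllib.parse.urlparse(source)
    if parsed.scheme in ("http", "https", "ftp"):
        cache_dir = cache_dir or os.path.join(os.path.expanduser("~"), ".cache", "hoplite")
        os.makedirs(cache_dir, exist_ok=True)
        key = hashlib.sha256(source.encode()).hexdigest()[:24]
        local = os.path.join(cache_dir, key + "_" + os.path.basename(parsed.path))
        if not os.path.exists(local):
            logger.info("downloading %s -> %s", source, local)
            try:
                urllib.request.urlretrieve(source, local)
            except OSError as exc:
                raise IOError(f"cannot fetch source {source!r}: {exc}") from exc
        return local
    if not os.path.exists(source):
        raise IOError(f"source file not found: {source!r}")
    return source


def _sniff_dialect(path: str) -> str:
    if path.endswith((".jsonl", ".jsonlines", ".ndjson", ".json")):
        return "jsonlines"
    if path.endswith((".tsv", ".txt")):
        return "tsv"
    with open(path, "rb") as fh:
        first = fh.read(1)
    return "jsonlines" if first == b"{" else "tsv"


def _iter_tsv(path: str) -> Iterator[tuple[int, dict[str, str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            return
        header = header_line.rstrip("\n").split("\t")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            values = line.split("\t")
            yield lineno, dict(zip(header, values))


def _iter_jsonl(path: str) -> Iterator[tuple[int, dict[str, Any]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                yield lineno, json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON ({exc})") from exc


def _coerce_property(key: str, value: Any, dialect: str, delimiter: str) -> Any:
    if dialect == "jsonlines":
        return value
    if key in _LIST_PROPERTIES:
        return parse_list_field(value, "tsv", delimiter)
    return value


def read_graph(nodes_source: str, edges_source: str, dialect: str = "auto",
               *, list_delimiter: str = DEFAULT_LIST_DELIMITER,
               equivalent_identifiers_property: str = "equivalent_identifiers",
               default_category: str = "NamedThing",
               cache_dir: str | None = None) -> Graph:
    """Load a knowledge graph from KGX nodes and edges files (path or URL).

    Parameters
    ----------
    dialect:
        ``tsv``, ``jsonlines``, or ``auto`` (sniff by extension, then by
        whether the first byte is ``{``).
    list_delimiter:
        Separator for multi-valued TSV fields.
    equivalent_identifiers_property:
        Name of the node property carrying equivalent CURIEs; exports vary.
    default_category:
        Category assigned to nodes whose category field is empty, keeping
        downstream indexing total.
    """
    nodes_path = _fetch(nodes_source, cache_dir)
    edges_path = _fetch(edges_source, cache_dir)
    node_dialect = _sniff_dialect(nodes_path) if dialect == "auto" else dialect
    edge_dialect = _sniff_dialect(edges_path) if dialect == "auto" else dialect

    graph = Graph(provenance={
        "nodes_source": nodes_source,
        "edges_source": edges_source,
        "dialect": {"nodes": node_dialect, "edges": edge_dialect},
        "warnings": {"dangling_edges": 0, "duplicate_nodes": 0,
                     "duplicate_edge_ids": 0, "defaulted_categories": 0},
    })
    warn = graph.provenance["warnings"]

    rows = _iter_tsv(nodes_path) if node_dialect == "tsv" else _iter_jsonl(nodes_path)
    for lineno, row in rows:
        node_id = row.get("id")
        if not node_id:
            raise FormatError(f"{nodes_path}:{lineno}: node row missing 'id'")
        raw_cats = row.get("category", row.get("categories"))
        if "category" not in row and "categories" not in row and node_dialect == "tsv":
            raise FormatError(f"{nodes_path}:{lineno}: node row missing 'category' column")
        categories = parse_list_field(raw_cats, node_dialect, list_delimiter)
        categories = [str(c) for c in categories]
        if not categories:
            categories = [default_category]
            warn["defaulted_categories"] += 1
        equivalents = parse_list_field(
            row.get(equivalent_identifiers_property), node_dialect, list_delimiter)
        properties = {
            k: _coerce_property(k, v, node_dialect, list_delimiter)
            for k, v in row.items()
            if k not in _NODE_CORE and k != equivalent_identifiers_property
            and v not in (None, "")
        }
        if node_id in graph.nodes:
            warn["duplicate_nodes"] += 1
            logger.warning("duplicate node id %r (line %d): keeping last", node_id, lineno)
        graph.nodes[node_id] = KnowledgeNode(
            id=node_id,
            name=str(row.get("name") or ""),
            categories=categories,
            equivalent_identifiers=[str(e) for e in equivalents],
            properties=properties,
        )

    rows = _iter_tsv(edges_path) if edge_dialect == "tsv" else _iter_jsonl(edges_path)
    for lineno, row in rows:
        missing = [k for k in ("subject", "predicate", "object") if not row.get(k)]
        if missing:
            raise FormatError(
                f"{edges_path}:{lineno}: edge row missing {', '.join(missing)}")
        subject, predicate, object_ = row["subject"], row["predicate"], row["object"]
        if subject not in graph.nodes or object_ not in graph.nodes:
            warn["dangling_edges"] += 1
            logger.warning("dropping dangling edge at line %d: %s -%s-> %s",
                           lineno, subject, predicate, object_)
            continue
        properties = {
            k: _coerce_property(k, v, edge_dialect, list_delimiter)
            for k, v in row.items()
            if k not in _EDGE_CORE and v not in (None, "")
        }
        edge_id = str(row.get("id") or "") or synthesize_edge_id(
            subject, predicate, object_, str(properties.get("primary_knowledge_source", "")))
        if edge_id in graph.edges:
            warn["duplicate_edge_ids"] += 1
            suffix = 2
            while f"{edge_id}--{suffix}" in graph.edges:
                suffix += 1
            edge_id = f"{edge_id}--{suffix}"
        graph.edges[edge_id] = KnowledgeEdge(
            id=edge_id, subject=subject, object=object_, predicate=predicate,
            properties=properties,
        )
    return graph


def read_edges(edges_source: str, dialect: str = "auto",
               *, list_delimiter: str = DEFAULT_LIST_DELIMITER,
               cache_dir: str | None = None) -> list[KnowledgeEdge]:
    """Load a standalone KGX edges file (no nodes file, no referential check).

    Used for external subclass-edge sources, whose endpoints typically refer
    to nodes of the main graph.
    """
    path = _fetch(edges_source, cache_dir)
    edge_dialect = _sniff_dialect(path) if dialect == "auto" else dialect
    rows = _iter_tsv(path) if edge_dialect == "tsv" else _iter_jsonl(path)
    edges: list[KnowledgeEdge] = []
    for lineno, row in rows:
        missing = [k for k in ("subject", "predicate", "object") if not row.get(k)]
        if missing:
            raise FormatError(f"{path}:{lineno}: edge row missing {', '.join(missing)}")
        properties = {
            k: _coerce_property(k, v, edge_dialect, list_delimiter)
            for k, v in row.items()
            if k not in _EDGE_CORE and v not in (None, "")
        }
        edge_id = str(row.get("id") or "") or synthesize_edge_id(
            row["subject"], row["predicate"], row["object"],
            str(properties.get("primary_knowledge_source", "")))
        edges.append(KnowledgeEdge(id=edge_id, subject=row["subject"],
                                   object=row["object"], predicate=row["predicate"],
                                   properties=properties))
    return edges


# ---------------------------------------------------------------------------
# writing


def _format_value(value: Any, delimiter: str) -> str:
    if isinstance(value, list):
        return delimiter.join(str(v) for v in value)
    return str(value)


def write_graph(graph: Graph, nodes_target: str, edges_target: str,
                dialect: str = "tsv",
                *, list_delimiter: str = DEFAULT_LIST_DELIMITER,
                equivalent_identifiers_property: str = "equivalent_identifiers") -> None:
    """Serialize *graph* so that ``read_graph`` round-trips it exactly."""
    if dialect == "jsonlines":
        with open(nodes_target, "w", encoding="utf-8") as fh:
            for nid in graph.nodes:
                n = graph.nodes[nid]
                obj: dict[str, Any] = {"id": n.id, "name": n.name, "category": n.categories}
                if n.equivalent_identifiers:
                    obj[equivalent_identifiers_property] = n.equivalent_identifiers
                obj.update(n.properties)
                fh.write(json.dumps(obj, sort_keys=True) + "\n")
        with open(edges_target, "w", encoding="utf-8") as fh:
            for eid in graph.edges:
                e = graph.edges[eid]
                obj = {"id": e.id, "subject": e.subject, "predicate": e.predicate,
                       "object": e.object}
                obj.update(e.properties)
                fh.write(json.dumps(obj, sort_keys=True) + "\n")
        return
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    node_props = sorted({k for n in graph.nodes.values() for k in n.properties})
    node_header = ["id", "name", "category", equivalent_identifiers_property] + node_props
    with open(nodes_target, "w", encoding="utf-8") as fh:
        fh.write("\t".join(node_header) + "\n")
        for n in graph.nodes.values():
            row = [n.id, n.name,
                   _format_value(n.categories, list_delimiter),
                   _format_value(n.equivalent_identifiers, list_delimiter)]
            row += [_format_value(n.properties.get(k, ""), list_delimiter)
                    for k in node_props]
            fh.write("\t".join(row) + "\n")

    edge_props = sorted({k for e in graph.edges.values() for k in e.properties})
    edge_header = ["id", "subject", "predicate", "object"] + edge_props
    with open(edges_target, "w", encoding="utf-8") as fh:
        fh.write("\t".join(edge_header) + "\n")
        for e in graph.edges.values():
            row = [e.id, e.subject, e.predicate, e.object]
            row += [_format_value(e.properties.get(k, ""), list_delimiter)
                    for k in edge_props]
            fh.write("\t".join(row) + "\n")
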