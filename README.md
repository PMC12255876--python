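# hoplite

An in-memory engine for serving biomedical knowledge graphs as standards-style
one-hop query APIs.

Biomedical knowledge graphs — drugs, diseases, genes, proteins and the edges
that relate them — are usually distributed as flat files in KGX format (a
nodes table plus an edges table, TSV or JSON Lines) and consumed through
TRAPI-shaped JSON APIs that answer *one-hop* pattern-matching queries: two
query nodes joined by one query edge, e.g. *Acetaminophen —interacts_with→
Protein?*. Answering such queries correctly is more than an edge lookup; the
engine must reason over the semantic model behind the graph:

1. **hierarchies** of node and edge types — asking for `affects` must also
   return `treats` edges, asking for `ChemicalEntity` neighbors must also
   return `Drug` nodes;
2. **symmetry** of edge types — an `interacts_with` edge must be found from
   either endpoint;
3. **canonicity** of edge types — `treated_by` edges are stored in their
   canonical `treats` direction and flipped back on demand;
4. **concept equivalence** — `DRUGBANK:DB00316` and `CHEBI:46195` both name
   acetaminophen and must answer for each other;
5. **transitive subclass chaining** — a query pinned to *pain disorder*
   answers with edges attached to *headache disorder* and its subclasses.

hoplite encodes all five reasoning tasks into its core data structure **at
build time** — a nested adjacency map
`node → neighbor category → predicate → direction → {(neighbor, edge)}`
with hierarchy/symmetry/canonicity expansion baked into the keys — so query
answering is constant-time dictionary lookup per answer edge, and response
time grows linearly with the number of edges in the answer. The trade-off is
memory: every edge is registered under all ancestor predicates and ancestor
categories of its endpoints.

Around this core the package provides:

- KGX reading/writing in both dialects with forgiving real-world policies
  (dangling edges dropped and counted, duplicate ids handled
  deterministically);
- optional **graph canonicalization**: union–find over
  `equivalent_identifiers` clusters (or a pluggable offline resolver), one
  node per cluster, edges re-pointed and deduplicated;
- persistent index **snapshots** so a service restart skips re-parsing;
- an automatically derived **meta knowledge graph** (schema-level summary
  with counts) and **test triples** (one exemplar edge per meta-edge);
- a multiplexed **web service** (stdlib WSGI, no framework) exposing any
  number of graphs at separate sub-endpoints, with debug endpoints and an
  authenticated background `/rebuild` that swaps state atomically;
- a **synthetic-graph generator** with planted hierarchies, equivalence
  clusters and subclass chains, plus an independent **brute-force oracle**
  that defines correctness for the indexed engine.

## Worked example

Given a five-node KGX graph (`nodes.tsv`, `edges.tsv`) where acetaminophen
(`CHEBI:46195`, with `DRUGBANK:DB00316` listed as an equivalent identifier)
physically interacts with PTGS1 and PTGS2 — one edge stored in each
direction — plus a `treated_by` edge and a disease subclass edge:

```python
from hoplite import (load_semantic_model, read_graph, build_equivalence_map,
                     build_index, build_subclass_closure, answer_query,
                     parse_query_graph)

model = load_semantic_model("tests/data/mini_model.yaml")
graph = read_graph("nodes.tsv", "edges.tsv")
eqmap = build_equivalence_map(graph, prefix_priority=["CHEBI", "DRUGBANK"])
subclass = build_subclass_closure(graph)
index = build_index(graph, model)

query = parse_query_graph({"message": {"query_graph": {
    "nodes": {"drug": {"ids": ["DRUGBANK:DB00316"]},
              "target": {"categories": ["biolink:Protein"]}},
    "edges": {"hit": {"subject": "drug", "object": "target",
                      "predicates": ["biolink:interacts_with"]}}}}})
response = answer_query(query, index, model, subclass, eqmap)
for result in response["message"]["results"]:
    drug = result["node_bindings"]["drug"][0]
    target = result["node_bindings"]["target"][0]
    edges = [b["id"] for b in result["analyses"][0]["edge_bindings"]["hit"]]
    print(drug["id"], "(asked as", drug.get("query_id"), ")",
          "--interacts_with->", target["id"], "via", edges)
print(response["description"])
```

prints

```
CHEBI:46195 (asked as DRUGBANK:DB00316 ) --interacts_with-> UniProtKB:P23219 via ['e1']
CHEBI:46195 (asked as DRUGBANK:DB00316 ) --interacts_with-> UniProtKB:P35354 via ['e2']
2 result(s), 2 edge(s)
```

Three reasoning features are visible in this output: the query pinned a
DRUGBANK CURIE but the graph node is the CHEBI member of its equivalence
cluster (hence the `query_id` annotation); the query asked for
`interacts_with` but the edges carry the more specific
`physically_interacts_with`; and edge `e2` is stored protein→drug, yet is
found from the drug side because the predicate is symmetric.

## Serving graphs over HTTP

Each graph is described by one JSON config file (see
`examples/config.template.json`); a directory of configs is served
multiplexed, one sub-endpoint per graph:

```bash
hoplite serve --config-dir configs/ --snapshot-dir snapshots/ --port 9990
```

Routes per graph: `POST /{endpoint_name}/query`,
`GET /{endpoint_name}/meta_knowledge_graph`,
`GET /{endpoint_name}/sri_test_triples`; application-wide:
`GET /code_version`, `GET /logs`, `GET /healthcheck`, and authenticated
`POST /rebuild` (re-reads sources in the background, then swaps the serving
state atomically). `examples/Dockerfile` packages the same entry point in a
container; the service also runs bare, as above.

Offline workflows use the same library through
`hoplite build --config FILE --snapshot-dir DIR` (index construction without
serving), `hoplite query --config FILE --query FILE` (one-shot answering) and
`hoplite synth --out DIR` (synthetic KGX graph generation).

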