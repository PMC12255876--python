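{
  "_comments": {
    "_": "Per-KG service configuration. Copy one file per graph into the --config-dir directory; unknown keys (like this block) are ignored.",
    "nodes_file": "Path or URL of the KGX nodes file (TSV or JSON Lines; URLs are downloaded to a local cache at build time).",
    "edges_file": "Path or URL of the KGX edges file.",
    "endpoint_name": "URL path segment this graph is served under, e.g. 'kg2c' -> POST /kg2c/query. Must be unique across configs.",
    "semantic_model": "Path to the semantic-model YAML/JSON (category/predicate hierarchies, symmetry, inverses, canonical flags).",
    "canonicalize": "If true, merge equivalent nodes into one node per cluster before indexing.",
    "trapi_attribute_map": "How edge/node properties are emitted as TRAPI attributes; unmapped properties fall back to the raw property name.",
    "subclass_sources": "Optional extra KGX edges files whose subclass edges are unioned into the subclass closure.",
    "subclass_predicates": "Predicates treated as subclass relations (default ['subclass_of']).",
    "preferred_prefix_order": "CURIE prefix priority for choosing cluster representatives.",
    "list_delimiter": "Separator for multi-valued fields in the TSV dialect (default '|').",
    "equivalent_identifiers_property": "Node property carrying equivalent CURIEs (exports vary).",
    "resolver_file": "Optional JSON table {curie: {members: [...], preferred: curie}} used for nodes that list no equivalents.",
    "rebuild_token_hash": "SHA-256 hex digest of the secret accepted by POST /rebuild; omit to disable the endpoint.",
    "kg_version": "Free-form version string reported by /code_version."
  },
  "nodes_file": "https://example.org/my-kg/nodes.tsv",
  "edges_file": "https://example.org/my-kg/edges.tsv",
  "endpoint_name": "mykg",
  "semantic_model": "semantic_model.yaml",
  "canonicalize": false,
  "trapi_attribute_map": {
    "publications": {
      "attribute_type_id": "biolink:publications",
      "value_type": "biolink:Publication"
    },
    "knowledge_level": {
      "attribute_type_id": "biolink:knowledge_level"
    }
  },
  "subclass_sources": [],
  "preferred_prefix_order": ["CHEBI", "DRUGBANK", "MONDO", "NCBIGene", "UniProtKB"],
  "list_delimiter": "|",
  "equivalent_identifiers_property": "equivalent_identifiers",
  "kg_version": "1.0"
}
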