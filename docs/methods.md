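# Methods

## The data model

A knowledge graph is a set of **nodes** keyed by CURIE (`CHEBI:46195`), each
with a name, an ordered category list (most specific first, by KGX
convention), optional `equivalent_identifiers`, and free-form properties;
and a set of **edges** keyed by an opaque id, each with subject, object, a
predicate, and properties (knowledge source, publications, ...). Graphs are
read from KGX flat files in either the TSV or JSON Lines dialect.

The **semantic model** is the reasoning substrate: two rooted DAGs (category
and predicate hierarchies, multiple parents allowed, as Biolink's mixins
require) plus three per-predicate facts — `symmetric`, `inverse`, and
`canonical` (which member of an inverse pair is the storage direction). The
file dialect is a flat YAML mapping rather than a full LinkML schema because
these are the only facts the engine consumes; a real Biolink release maps
onto it by exporting each class/slot's `is_a`+mixin parents and the
`symmetric`/`inverse`/`canonical_predicate` slot annotations. Validation is
strict and fatal: dangling parents, hierarchy cycles, asymmetric inverse
declarations, inverse pairs without exactly one canonical member, and
symmetric predicates with inverses are all rejected at load. Names are
matched case-sensitively after stripping an optional `biolink:` prefix and
emitted prefixed.

## The index and its reasoning semantics

The core structure is

```
adj[node][neighbor_category][predicate][direction] -> {(neighbor, edge_id)}
```

Build-time expansion trades memory for constant-time lookup:

- every edge is first rewritten to **canonical form** — the non-canonical
  member of an inverse pair becomes its inverse with subject/object swapped
  (the flip is recorded on the edge);
- the pair is registered under the canonical predicate **and all its
  ancestors**, and under **every listed category of the neighbor plus all
  their ancestors**;
- symmetric-predicate edges are registered from both endpoints in direction
  `out` (direction is meaningless for them); directional edges get `out` at
  the subject and `in` at the object.

Query answering then expands query predicates to their descendant sets, maps
each through canonical form (remembering per-predicate flips), and performs
plain lookups — no descendant walks at query time.

Two corner cases needed an explicit semantic decision because hierarchy,
symmetry and canonicity can interact (a directional predicate under a
symmetric ancestor, or vice versa — legal in this package's schema dialect
even though Biolink itself keeps symmetric sub-hierarchies symmetric):

1. **a symmetric query predicate matches in both orientations**, including
   for directional descendant edges (the query's direction carries no
   meaning when the asked-for predicate is symmetric);
2. **a symmetric stored edge matches in both orientations** under any query
   predicate it descends from, including flipped (non-canonical) ones.

Both rules are implemented independently in the engine (as lookup-direction
choices plus one per-edge symmetry filter) and in the brute-force oracle,
and the acceptance property holds them to exact agreement.

Edges whose predicate is unknown to the model are indexed under the root
predicate with a counted warning — the build is total over imperfect
inputs. Nodes with no category are assigned the root category at load, and
node categories unknown to the model fall back to the root category for
indexing purposes.

## Concept equivalence and canonicalization

Equivalence clusters are computed by union–find (path compression,
deterministic sorted iteration) over each node's
`{id} ∪ equivalent_identifiers`. Nodes listing no equivalents may be
resolved by a pluggable resolver honoring a Node-Normalizer-style batch
contract; the shipped implementation is a file-backed offline stub, and
resolver failure degrades to singleton clusters so builds never require
network access. Cluster representatives are chosen by configured
prefix-priority order, with ties broken by lexicographic CURIE order
(textual, so `X:10` beats `X:2` — documented precisely because it is
surprising).

Canonicalization (optional, per config) merges each cluster to one node
keyed by the representative: categories union in first-seen order, the
representative's scalar properties win (conflicting values from other
members are stashed under `_merged_values`), list properties concatenate
and deduplicate. Edges are re-pointed to representatives; duplicates under
`(subject, object, predicate, primary_knowledge_source)` merge; self-loops
created by merging are kept. The operation is idempotent.

Queries pinned to *any* CURIE of a cluster resolve to **all cluster members
present in the graph plus the transitive subclass descendants of each
member**. On a canonicalized graph this is exactly "the representative plus
its subclass descendants"; on a non-canonicalized graph it also finds
members that are themselves graph nodes. Answers whose bound node differs
from the asked CURIE carry a `query_id` annotation naming the original.

## Subclass closure

`descendants_of[x]` is every node reachable from `x` against one or more
`subclass_of`-style edges (predicate set configurable; an external KGX edge
file may be unioned in). Chaining is unbounded by default, with an optional
depth guard for pathological graphs. Cycles terminate and collapse: members
of a cycle are descendants of each other but never of themselves. Subclass
edges remain ordinary queryable edges.

## Meta knowledge graph and test triples

Meta-edges aggregate the **stored canonical** edges (one entry per input
edge — expanded index entries would inflate counts) under each endpoint's
most specific category, taken as the first entry of the node's category
list; with single-category nodes, counts therefore sum exactly to the
stored edge count. A configurable `all_categories` mode uses every listed
category pair instead, relaxing that sum. Per-category `id_prefixes` are
the observed CURIE prefixes ordered by frequency then name. Test triples
pick, per meta-edge, the exemplar edge whose seed-keyed hash orders
smallest — deterministic for a fixed seed, re-sampleable by changing it.

## Service layer

The web layer is a plain WSGI application on the standard library's
threaded server; per-graph state (index, closure, equivalence map, meta-KG,
triples) is read-only after build, so any number of handler threads share
it without locking. `/rebuild` (enabled only when a SHA-256 token hash is
configured; compared constant-time) runs the full build pipeline in a
background thread and replaces the whole state object in one assignment
under a lock — requests see entirely-old or entirely-new state, never a
mixture. One graph failing to build marks only that endpoint failed
(reported by `/healthcheck`); others still serve. The log endpoint returns
the last 500 lines of an in-memory ring buffer, never raw files.

Snapshots are a versioned directory of deterministic JSON files plus a
manifest (format version, per-file SHA-256 checksums, build metadata); load
errors distinguish missing, version-mismatched and corrupt snapshots.

## Synthetic data and the oracle

The generator emulates the *structural* features the engine reasons over,
not real biology: random category/predicate DAGs of controlled depth, a
controlled mix of symmetric predicates (default 20%) and canonical inverse
pairs (default 30%), equivalence clusters of size 2–3 planted via mutual
`equivalent_identifiers` over ~15% of nodes, subclass chains planted as
`subclass_of` edges, and edges drawn uniformly over node pairs with
realistic property shapes (knowledge source, publication lists). Defaults
(50 nodes, 150 edges) keep single graphs sub-millisecond to build; the
oracle-agreement property runs them up to 200 nodes / 1000 edges. Degree
distributions, ontology realism and attribute-value realism are *not*
emulated, so passing tests demonstrate reasoning correctness and scaling —
not retrieval quality on any real graph. Draws come from independent
seeded sub-streams per concern, so a fixed seed is byte-reproducible and
extending one concern does not perturb the others.

`brute_force_answer` is the referee: it re-states one-hop matching from
first principles — per-edge iteration, on-the-fly hierarchy walks, naive
equivalence/subclass reachability, its own constraint evaluator — and
shares no expansion code with the index or query modules.

## Numerical and procedural choices

- **Determinism everywhere**: sorted iteration orders, sorted JSON keys,
  results ordered by (subject, object) binding, edge bindings sorted.
  Identical inputs give byte-identical outputs, which is what makes the
  32-concurrent-clients identity check meaningful.
- **Attribute constraints**: `==` is membership when either side is a list;
  `matches` is regular-expression search; `>`/`<` coerce both operands with
  `float()` and surface failures as client errors; a missing property
  leaves a constraint unsatisfied *before* negation.
- **Pinned-side choice**: when both query nodes are pinned, matching starts
  from the side with fewer resolved concrete ids (ties go to the query-edge
  subject); the other side is applied as an intersection filter.
- **Scaling measurement**: star graphs with one hub and 10–100 000 leaf
  edges; per size, the median of three timed `answer_query` calls with the
  garbage collector quiesced (collected before, disabled during) so
  allocation spikes do not masquerade as asymptotic growth; slope from a
  least-squares fit on log10/log10 over nine log-spaced sizes.
- **Fully unpinned queries are rejected** at validation: they enumerate the
  whole graph and no lookup-style client needs them.

## Known limitations

- The engine answers one-hop queries only; multi-hop planning, TRAPI
  qualifier constraints, result scoring and asynchronous callbacks are out
  of scope (downstream reasoning agents provide them).
- Build-time expansion is memory-hungry by design; there is no streaming or
  memory-mapped index, so graph size is bounded by RAM.
- Subclass-derived and equivalence-derived answers are flagged only via
  `query_id` on node bindings; no auxiliary support graphs are fabricated.
- The TRAPI response dialect is the `results`/`analyses`/`edge_bindings`
  nesting with exactly one analysis per result; clients expecting older
  flat shapes need an adapter.
- The semantic-model dialect carries hierarchy/symmetry/canonicity facts
  only; LinkML slot qualifiers, mixin semantics beyond multi-parent edges
  and version negotiation are not parsed.
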