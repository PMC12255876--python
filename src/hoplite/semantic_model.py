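"""Semantic-model substrate: category/predicate hierarchies and predicate properties.

The semantic model plays the role the Biolink Model plays for production
biomedical knowledge graphs: it declares the category (node-type) and
predicate (edge-type) hierarchies, plus three per-predicate facts that drive
reasoning at index-build and query time:

* ``symmetric`` -- the predicate reads the same in both directions
  (e.g. ``interacts_with``), so edges are retrievable from either endpoint;
* ``inverse`` -- the predicate naming the reverse reading
  (``treats`` / ``treated_by``);
* ``canonical`` -- which member of an inverse pair is the storage direction.

The on-disk dialect is a flat YAML (or JSON) mapping -- see ``load_semantic_model``
-- rather than a full LinkML schema: only hierarchy, symmetry and canonicity
facts are needed here.  A real Biolink release maps onto it by exporting, for
each class and slot, its ``is_a``/mixin parents and the ``symmetric``,
``inverse`` and ``annotations.canonical_predicate`` slot properties.

Names are compared case-sensitively after stripping an optional ``biolink:``
prefix; both prefixed and bare forms are accepted on input, and external
serializations (TRAPI responses, the meta knowledge graph) emit the prefixed
form.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

__all__ = [
    "SemanticModel",
    "SchemaError",
    "UnknownNameError",
    "load_semantic_model",
    "strip_prefix",
    "add_prefix",
]

_PREFIX = "biolink:"


class SchemaError(ValueError):
    """The semantic-model file violates a structural invariant."""


class UnknownNameError(KeyError):
    """A category or predicate name is not declared in the model."""


def strip_prefix(name: str) -> str:
    """Normalize a category/predicate name to its bare form."""
    return name[len(_PREFIX):] if name.startswith(_PREFIX) else name


def add_prefix(name: str) -> str:
    """Emit a category/predicate name in prefixed form."""
    return name if name.startswith(_PREFIX) else _PREFIX + name


@dataclass
class _Category:
    parents: list[str] = field(default_factory=list)


@dataclass
class _Predicate:
    parents: list[str] = field(default_factory=list)
    symmetric: bool = False
    inverse: str | None = None
    canonical: bool = False


@dataclass
class SemanticModel:
    """Validated category/predicate hierarchy DAGs plus predicate properties.

    Descendant sets are precomputed at load time so hierarchy expansion is a
    dictionary lookup for the index builder and the query layer.
    """

    categories: dict[str, _Category]
    predicates: dict[str, _Predicate]
    category_prefixes: dict[str, list[str]]
    root_category: str
    root_predicate: str
    _category_descendants: dict[str, frozenset[str]] = field(repr=False, default_factory=dict)
    _predicate_descendants: dict[str, frozenset[str]] = field(repr=False, default_factory=dict)
    _category_ancestors: dict[str, frozenset[str]] = field(repr=False, default_factory=dict)
    _predicate_ancestors: dict[str, frozenset[str]] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._category_descendants:
            self._category_descendants, self._category_ancestors = _closures(
                {n: c.parents for n, c in self.categories.items()}
            )
            self._predicate_descendants, self._predicate_ancestors = _closures(
                {n: p.parents for n, p in self.predicates.items()}
            )

    # -- hierarchy queries ------------------------------------------------

    def category_descendants(self, category: str) -> frozenset[str]:
        """Inclusive transitive-descendant set of *category*."""
        name = strip_prefix(category)
        try:
            return self._category_descendants[name]
        except KeyError:
            raise UnknownNameError(f"unknown category: {category!r}") from None

    def predicate_descendants(self, predicate: str) -> frozenset[str]:
        """Inclusive transitive-descendant set of *predicate*."""
        name = strip_prefix(predicate)
        try:
            return self._predicate_descendants[name]
        except KeyError:
            raise UnknownNameError(f"unknown predicate: {predicate!r}") from None

    def category_ancestors(self, category: str) -> frozenset[str]:
        """Inclusive transitive-ancestor set of *category*."""
        name = strip_prefix(category)
        try:
            return self._category_ancestors[name]
        except KeyError:
            raise UnknownNameError(f"unknown category: {category!r}") from None

    def predicate_ancestors(self, predicate: str) -> frozenset[str]:
        """Inclusive transitive-ancestor set of *predicate*."""
        name = strip_prefix(predicate)
        try:
            return self._predicate_ancestors[name]
        except KeyError:
            raise UnknownNameError(f"unknown predicate: {predicate!r}") from None

    # -- predicate properties ---------------------------------------------

    def _predicate(self, predicate: str) -> _Predicate:
        name = strip_prefix(predicate)
        try:
            return self.predicates[name]
        except KeyError:
            raise UnknownNameError(f"unknown predicate: {predicate!r}") from None

    def is_symmetric(self, predicate: str) -> bool:
        """Whether *predicate* is declared symmetric."""
        return self._predicate(predicate).symmetric

    def canonical_form(self, predicate: str) -> tuple[str, bool]:
        """Map *predicate* to its canonical storage form.

        Returns ``(canonical_predicate, flipped)``.  Canonical and symmetric
        predicates map to themselves with ``flipped=False``; the non-canonical
        member of an inverse pair maps to its inverse with ``flipped=True``,
        signalling that subject and object must be swapped.
        """
        name = strip_prefix(predicate)
        rec = self._predicate(name)
        if rec.symmetric or rec.canonical or rec.inverse is None:
            return name, False
        return rec.inverse, True

    def has_category(self, category: str) -> bool:
        return strip_prefix(category) in self.categories

    def has_predicate(self, predicate: str) -> bool:
        return strip_prefix(predicate) in self.predicates


def _closures(
    parents_of: Mapping[str, Iterable[str]],
) -> tuple[dict[str, frozenset[str]], dict[str, frozenset[str]]]:
    """Reflexive-transitive descendant and ancestor sets over a parent map."""
    children_of: dict[str, set[str]] = {n: set() for n in parents_of}
    for name, parents in parents_of.items():
        for p in parents:
            children_of[p].add(name)

    def reach(start: str, succ: Mapping[str, set[str]]) -> frozenset[str]:
        seen = {start}
        queue = deque([start])
        while queue:
            for nxt in succ[queue.popleft()]:
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append(nxt)
        return frozenset(seen)

    parent_sets = {n: set(ps) for n, ps in parents_of.items()}
    descendants = {n: reach(n, children_of) for n in parents_of}
    ancestors = {n: reach(n, parent_sets) for n in parents_of}
    return descendants, ancestors


def _validate_dag(parents_of: Mapping[str, list[str]], kind: str) -> None:
    for name, parents in parents_of.items():
        for p in parents:
            if p not in parents_of:
                raise SchemaError(
                    f"{kind} {name!r} lists parent {p!r}, which is not declared"
                )
    # iterative DFS cycle detection, reporting one cycle
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {n: WHITE for n in parents_of}
    for start in parents_of:
        if color[start] != WHITE:
            continue
        stack: list[tuple[str, int]] = [(start, 0)]
        path = [start]
        color[start] = GRAY
        while stack:
            node, i = stack[-1]
            parents = parents_of[node]
            if i < len(parents):
                stack[-1] = (node, i + 1)
                nxt = parents[i]
                if color[nxt] == GRAY:
                    cycle = path[path.index(nxt):] + [nxt]
                    raise SchemaError(
                        f"{kind} hierarchy contains a cycle: {' -> '.join(cycle)}"
                    )
                if color[nxt] == WHITE:
                    color[nxt] = GRAY
                    stack.append((nxt, 0))
                    path.append(nxt)
            else:
                color[node] = BLACK
                stack.pop()
                path.pop()


def _find_root(parents_of: Mapping[str, list[str]], kind: str) -> str:
    roots = sorted(n for n, ps in parents_of.items() if not ps)
    if len(roots) != 1:
        raise SchemaError(
            f"expected exactly one parentless root {kind}, found {roots or 'none'}"
        )
    return roots[0]


def load_semantic_model(path: str) -> SemanticModel:
    """Load and validate a semantic-model file.

    The file is YAML (JSON is a YAML subset) with top-level keys
    ``categories``, ``predicates`` and optional ``category_prefixes``::

        categories:
          NamedThing: {}
          ChemicalEntity: {parents: [NamedThing]}
        predicates:
          related_to: {}
          treats: {parents: [related_to], canonical: true, inverse: treated_by}
          treated_by: {parents: [related_to], inverse: treats}
          interacts_with: {parents: [related_to], symmetric: true}
        category_prefixes:
          ChemicalEntity: [CHEBI, DRUGBANK]

    Validation failures raise :class:`SchemaError`; they are fatal by design
    since every downstream reasoning step trusts the model.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "categories" not in raw or "predicates" not in raw:
        raise SchemaError(f"{path}: expected top-level 'categories' and 'predicates' maps")

    categories: dict[str, _Category] = {}
    for name, rec in (raw["categories"] or {}).items():
        rec = rec or {}
        categories[strip_prefix(name)] = _Category(
            parents=[strip_prefix(p) for p in rec.get("parents", [])]
        )
    predicates: dict[str, _Predicate] = {}
    for name, rec in (raw["predicates"] or {}).items():
        rec = rec or {}
        inverse = rec.get("inverse")
        predicates[strip_prefix(name)] = _Predicate(
            parents=[strip_prefix(p) for p in rec.get("parents", [])],
            symmetric=bool(rec.get("symmetric", False)),
            inverse=strip_prefix(inverse) if inverse else None,
            canonical=bool(rec.get("canonical", False)),
        )

    if not categories:
        raise SchemaError(f"{path}: no categories declared")
    if not predicates:
        raise SchemaError(f"{path}: no predicates declared")

    cat_parents = {n: c.parents for n, c in categories.items()}
    pred_parents = {n: p.parents for n, p in predicates.items()}
    _validate_dag(cat_parents, "category")
    _validate_dag(pred_parents, "predicate")

    for name, rec in predicates.items():
        if rec.inverse is None:
            continue
        if rec.symmetric:
            raise SchemaError(f"symmetric predicate {name!r} must not declare an inverse")
        inv = predicates.get(rec.inverse)
        if inv is None:
            raise SchemaError(f"predicate {name!r} declares unknown inverse {rec.inverse!r}")
        if inv.inverse != name:
            raise SchemaError(
                f"inverse pair asymmetry: {name!r}.inverse={rec.inverse!r} but "
                f"{rec.inverse!r}.inverse={inv.inverse!r}"
            )
        if inv.symmetric:
            raise SchemaError(f"symmetric predicate {rec.inverse!r} must not declare an inverse")
        if rec.canonical == inv.canonical:
            raise SchemaError(
                f"inverse pair ({name!r}, {rec.inverse!r}) must have exactly one "
                f"canonical member"
            )

    prefixes = {
        strip_prefix(k): list(v)
        for k, v in (raw.get("category_prefixes") or {}).items()
    }
    for k in prefixes:
        if k not in categories:
            raise SchemaError(f"category_prefixes names unknown category {k!r}")

    return SemanticModel(
        categories=categories,
        predicates=predicates,
        category_prefixes=prefixes,
        root_category=_find_root(cat_parents, "category"),
        root_predicate=_find_root(pred_parents, "predicate"),
    )
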