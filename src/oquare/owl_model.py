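"""Assertion-level data model of OWL 2 ontologies.

The quality metrics downstream are ratios of *assertion occurrence* counts,
not counts of declared entities: a datatype property with two ``rdfs:domain``
triples contributes two datatype-property assertions, and a class carrying
three annotation triples contributes three annotation assertions.
:class:`OntologyGraph` therefore stores per-class tallies of assertion
occurrences rather than entity sets.

Conventions (all on *asserted* axioms; no reasoning, no import resolution):

* ``classes`` holds named classes only; anonymous class expressions are
  never counted as classes.
* ``subclass_edges`` holds distinct asserted subclass axioms between two
  named classes.  Asserted ``A rdfs:subClassOf owl:Thing`` axioms are
  recorded separately in ``thing_children`` and excluded from edge totals,
  so metric denominators do not depend on whether a serializer asserts
  Thing-parenthood.  Exact duplicate axioms count once.
* A property *usage* is either an ``rdfs:domain`` declaration on a named
  class or an ``owl:onProperty`` occurrence inside a restriction attached to
  a named class; both tally to that class.
* Restrictions (existential, universal, cardinality, hasValue) reached from
  a named class via a subclass or equivalent-class axiom — directly or as
  operands of intersection/union/complement expressions — tally once per
  occurrence.  Equivalent-class axioms never create subclass edges.
* Class-membership assertions ``x rdf:type C`` tally to ``C``; annotation
  assertions whose subject is a named class tally to that class.

Classes with no asserted named superclass are implicitly rooted at
``owl:Thing`` for path computations only.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Union

import networkx as nx
from rdflib import BNode, Graph as _RDFGraph, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, RDF, RDFS

#: IRI of the root class; the implicit attachment point of orphan classes.
THING: str = str(OWL.Thing)

#: Built-in annotation properties always recognised, in addition to any
#: property explicitly typed owl:AnnotationProperty in the document.
_BUILTIN_ANNOTATION_PROPS = frozenset(
    str(p)
    for p in (
        RDFS.label,
        RDFS.comment,
        RDFS.seeAlso,
        RDFS.isDefinedBy,
        OWL.versionInfo,
        OWL.deprecated,
    )
)


class OWLParseError(ValueError):
    """Raised when a document is not well-formed RDF/XML carrying OWL."""


class CyclicHierarchyError(ValueError):
    """Raised when the asserted subclass hierarchy contains a cycle."""

    def __init__(self, cycle: list[tuple[str, str]]):
        self.cycle = cycle
        chain = " -> ".join(edge[0] for edge in cycle) + " -> " + cycle[-1][1]
        super().__init__(f"cyclic subclass hierarchy: {chain}")


def _normalize_tally(tally: Mapping[str, int] | None, classes: frozenset[str], what: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for cls, count in (tally or {}).items():
        if cls not in classes:
            raise ValueError(f"{what} tally references unknown class {cls!r}")
        if not isinstance(count, (int,)) or count < 0:
            raise ValueError(f"{what} tally for {cls!r} must be a nonnegative integer, got {count!r}")
        if count:
            out[cls] = int(count)
    return out


@dataclass(frozen=True)
class OntologyGraph:
    """Parsed asserted content of one OWL ontology.

    Per-class tallies map class IRI -> occurrence count; totals are exposed
    as properties and always equal the sum of the per-class tallies.
    """

    classes: frozenset[str]
    subclass_edges: tuple[tuple[str, str], ...] = ()
    thing_children: frozenset[str] = frozenset()
    object_property_assertions: Mapping[str, int] = field(default_factory=dict)
    datatype_property_assertions: Mapping[str, int] = field(default_factory=dict)
    restrictions: Mapping[str, int] = field(default_factory=dict)
    individuals: Mapping[str, int] = field(default_factory=dict)
    annotation_assertions: Mapping[str, int] = field(default_factory=dict)
    ontology_iri: str | None = None

    def __post_init__(self) -> None:
        classes = frozenset(self.classes)
        if THING in classes:
            raise ValueError("owl:Thing must not be a member of `classes`")
        edges = sorted(set(map(tuple, self.subclass_edges)))
        for child, parent in edges:
            if child == parent:
                raise ValueError(f"self subclass edge on {child!r}")
            if child not in classes or parent not in classes:
                raise ValueError(f"subclass edge ({child!r}, {parent!r}) has endpoint outside `classes`")
        thing_children = frozenset(self.thing_children)
        if not thing_children <= classes:
            raise ValueError("thing_children must be a subset of `classes`")
        object.__setattr__(self, "classes", classes)
        object.__setattr__(self, "subclass_edges", tuple(edges))
        object.__setattr__(self, "thing_children", thing_children)
        for name in (
            "object_property_assertions",
            "datatype_property_assertions",
            "restrictions",
            "individuals",
            "annotation_assertions",
        ):
            object.__setattr__(self, name, _normalize_tally(getattr(self, name), classes, name))

    # -- totals ---------------------------------------------------------

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_subclass_edges(self) -> int:
        return len(self.subclass_edges)

    @property
    def n_object_property_assertions(self) -> int:
        return sum(self.object_property_assertions.values())

    @property
    def n_datatype_property_assertions(self) -> int:
        return sum(self.datatype_property_assertions.values())

    @property
    def n_restrictions(self) -> int:
        return sum(self.restrictions.values())

    @property
    def n_individuals(self) -> int:
        return sum(self.individuals.values())

    @property
    def n_annotation_assertions(self) -> int:
        return sum(self.annotation_assertions.values())

    def counts(self) -> dict[str, int]:
        """All scalar counts, for round-trip comparisons."""
        return {
            "classes": self.n_classes,
            "subclass_edges": self.n_subclass_edges,
            "thing_children": len(self.thing_children),
            "object_property_assertions": self.n_object_property_assertions,
            "datatype_property_assertions": self.n_datatype_property_assertions,
            "restrictions": self.n_restrictions,
            "individuals": self.n_individuals,
            "annotation_assertions": self.n_annotation_assertions,
        }


def _load_rdf(document: Union[bytes, str, os.PathLike, IO[bytes]]) -> _RDFGraph:
    rg = _RDFGraph()
    try:
        if isinstance(document, bytes):
            rg.parse(data=document, format="xml")
        elif hasattr(document, "read"):
            rg.parse(file=document, format="xml")
        else:
            rg.parse(location=os.fspath(document), format="xml")
    except Exception as exc:  # rdflib raises SAXParseException et al.
        raise OWLParseError(f"not well-formed RDF/XML: {exc}") from exc
    return rg


def _restriction_operands(rg: _RDFGraph, node) -> Iterable:
    """Yield restriction nodes reachable as operands of a class expression."""
    if (node, RDF.type, OWL.Restriction) in rg or next(rg.objects(node, OWL.onProperty), None) is not None:
        yield node
        return
    for pred in (OWL.intersectionOf, OWL.unionOf):
        for lst in rg.objects(node, pred):
            for member in Collection(rg, lst):
                yield from _restriction_operands(rg, member)
    for comp in rg.objects(node, OWL.complementOf):
        yield from _restriction_operands(rg, comp)


def parse_owl(document: Union[bytes, str, os.PathLike, IO[bytes]]) -> OntologyGraph:
    """Parse an OWL 2 RDF/XML document into an :class:`OntologyGraph`.

    ``document`` may be raw bytes, a filesystem path, or a binary stream.
    ``owl:imports`` are never resolved; only the document's own axioms are
    counted.  A document with zero classes yields a valid empty graph.

    Raises
    ------
    OWLParseError
        If the document is not well-formed RDF/XML (the message names the
        offending location when the XML parser reports one).
    """
    rg = _load_rdf(document)

    named_classes: set[str] = {str(s) for s in rg.subjects(RDF.type, OWL.Class) if isinstance(s, URIRef)}
    # Undeclared named classes used in subclass axioms still count as classes.
    for s, o in rg.subject_objects(RDFS.subClassOf):
        if isinstance(s, URIRef) and str(s) != THING:
            named_classes.add(str(s))
        if isinstance(o, URIRef) and str(o) != THING:
            named_classes.add(str(o))
    named_classes.discard(THING)

    dt_props = {str(p) for p in rg.subjects(RDF.type, OWL.DatatypeProperty)}
    obj_props = {str(p) for p in rg.subjects(RDF.type, OWL.ObjectProperty)}
    ann_props = {str(p) for p in rg.subjects(RDF.type, OWL.AnnotationProperty)} | _BUILTIN_ANNOTATION_PROPS

    edges: set[tuple[str, str]] = set()
    thing_children: set[str] = set()
    obj_tally: dict[str, int] = defaultdict(int)
    dt_tally: dict[str, int] = defaultdict(int)
    restr_tally: dict[str, int] = defaultdict(int)

    def _count_restriction(cls: str, rnode) -> None:
        restr_tally[cls] += 1
        prop = next(rg.objects(rnode, OWL.onProperty), None)
        if prop is None:
            return
        if str(prop) in dt_props:
            dt_tally[cls] += 1
        else:  # untyped properties default to object properties
            obj_tally[cls] += 1

    for s, o in rg.subject_objects(RDFS.subClassOf):
        if not isinstance(s, URIRef) or str(s) not in named_classes:
            continue
        cls = str(s)
        if isinstance(o, URIRef):
            if str(o) == THING:
                thing_children.add(cls)
            elif str(o) != cls:
                edges.add((cls, str(o)))
        elif isinstance(o, BNode):
            for rnode in _restriction_operands(rg, o):
                _count_restriction(cls, rnode)

    for s, o in rg.subject_objects(OWL.equivalentClass):
        if isinstance(s, URIRef) and str(s) in named_classes and isinstance(o, BNode):
            for rnode in _restriction_operands(rg, o):
                _count_restriction(str(s), rnode)

    for p, c in rg.subject_objects(RDFS.domain):
        if not (isinstance(c, URIRef) and str(c) in named_classes):
            continue
        if str(p) in dt_props:
            dt_tally[str(c)] += 1
        else:
            obj_tally[str(c)] += 1

    not_individuals = named_classes | dt_props | obj_props | ann_props
    ind_tally: dict[str, int] = defaultdict(int)
    for x, c in rg.subject_objects(RDF.type):
        if isinstance(c, URIRef) and str(c) in named_classes and str(x) not in not_individuals:
            ind_tally[str(c)] += 1

    ann_tally: dict[str, int] = defaultdict(int)
    for s, p, o in rg:
        if isinstance(s, URIRef) and str(s) in named_classes and str(p) in ann_props:
            ann_tally[str(s)] += 1

    ontology_iri = None
    for onto in sorted(rg.subjects(RDF.type, OWL.Ontology)):
        if isinstance(onto, URIRef):
            ontology_iri = str(onto)
            break

    return OntologyGraph(
        classes=frozenset(named_classes),
        subclass_edges=tuple(edges),
        thing_children=frozenset(thing_children),
        object_property_assertions=dict(obj_tally),
        datatype_property_assertions=dict(dt_tally),
        restrictions=dict(restr_tally),
        individuals=dict(ind_tally),
        annotation_assertions=dict(ann_tally),
        ontology_iri=ontology_iri,
    )


def check_acyclic(g: OntologyGraph) -> None:
    """Raise :class:`CyclicHierarchyError` if the subclass hierarchy cycles."""
    dg = nx.DiGraph()
    dg.add_nodes_from(g.classes)
    dg.add_edges_from(g.subclass_edges)  # child -> parent
    if not nx.is_directed_acyclic_graph(dg):
        cycle = [(str(u), str(v)) for u, v, _ in nx.find_cycle(dg, orientation="original")]
        raise CyclicHierarchyError(cycle)


def root_to_leaf_paths(g: OntologyGraph) -> list[tuple[str, ...]]:
    """Enumerate every distinct directed path from ``owl:Thing`` to a leaf.

    Each path is a class sequence starting with :data:`THING`; its length in
    edges is ``len(path) - 1`` and includes the implicit (or asserted)
    attachment of top classes to the root.  Leaves are classes with no
    asserted subclasses; classes with no asserted named superclass attach
    directly under the root.

    Raises
    ------
    CyclicHierarchyError
        If the asserted subclass edges contain a cycle (one cycle is named).
    """
    check_acyclic(g)
    children: dict[str, list[str]] = defaultdict(list)
    has_named_parent: set[str] = set()
    for child, parent in g.subclass_edges:
        children[parent].append(child)
        has_named_parent.add(child)
    for kids in children.values():
        kids.sort()
    roots = sorted(c for c in g.classes if c not in has_named_parent)

    paths: list[tuple[str, ...]] = []

    def dfs(node: str, acc: list[str]) -> None:
        kids = children.get(node)
        if not kids:
            paths.append(tuple(acc))
            return
        for kid in kids:
            acc.append(kid)
            dfs(kid, acc)
            acc.pop()

    for root in roots:
        dfs(root, [THING, root])
    return paths


def path_length(path: tuple[str, ...]) -> int:
    """Length of a root-to-leaf path in edges."""
    return len(path) - 1
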