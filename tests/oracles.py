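"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exhaustive recursion over raw edge
lists and exact rational arithmetic via fractions.Fraction.  None of it
shares code with the package's metric or path computations.
"""

from __future__ import annotations

from fractions import Fraction

from oquare.owl_model import OntologyGraph


def brute_force_paths(g: OntologyGraph) -> list[tuple[str, ...]]:
    """All root-to-leaf class sequences (excluding the Thing sentinel)."""
    edges = list(g.subclass_edges)
    children = {}
    for child, parent in edges:
        children.setdefault(parent, []).append(child)
    has_parent = {child for child, _ in edges}
    roots = sorted(set(g.classes) - has_parent)

    out: list[tuple[str, ...]] = []

    def walk(node, prefix):
        kids = sorted(children.get(node, []))
        if not kids:
            out.append(tuple(prefix))
            return
        for kid in kids:
            walk(kid, prefix + [kid])

    for root in roots:
        walk(root, [root])
    return out


def brute_force_metrics(g: OntologyGraph) -> dict[str, Fraction | int]:
    """The twelve metrics as exact rationals, from first principles."""
    n = len(g.classes)
    assert n >= 1
    paths = brute_force_paths(g)
    # path length counts the implicit Thing attachment edge
    lengths = [len(p) for p in paths]
    edges = list(g.subclass_edges)
    n_edges = len(edges)
    props = sum(g.object_property_assertions.values()) + sum(g.datatype_property_assertions.values())

    parents_of = {}
    for child, parent in edges:
        parents_of.setdefault(child, set()).add(parent)
    has_child = {parent for _, parent in edges}
    leaves = [c for c in g.classes if c not in has_child]
    nac = Fraction(sum(len(parents_of.get(leaf, ())) or 1 for leaf in leaves), len(leaves))
    non_top = [c for c in g.classes if c in parents_of]
    return {
        "LCOMOnto": Fraction(sum(lengths), len(paths)),
        "WMCOnto": Fraction(props + n_edges, n),
        "DITOnto": max(lengths),
        "NACOnto": nac,
        "NOCOnto": Fraction(n_edges, len(non_top)) if non_top else Fraction(0),
        "RFCOnto": Fraction(props, n),
        "NOMOnto": Fraction(props, n),
        "PROnto": Fraction(props, n_edges + props) if n_edges + props else Fraction(0),
        "AROnto": Fraction(sum(g.restrictions.values()), n),
        "INROnto": Fraction(n_edges, n),
        "CROnto": Fraction(sum(g.individuals.values()), n),
        "ANOnto": Fraction(sum(g.annotation_assertions.values()), n),
    }


def random_dag_graph(rng, max_classes: int = 50) -> OntologyGraph:
    """A random acyclic ontology graph, built independently of GeneratorSpec."""
    n = int(rng.integers(1, max_classes + 1))
    names = [f"http://x.org/o#N{i}" for i in range(n)]
    edges = set()
    for i in range(1, n):
        for j in rng.choice(i, size=min(i, 1 + int(rng.integers(0, 3))), replace=False):
            if rng.random() < 0.7:
                edges.add((names[i], names[int(j)]))
    def tally(rate):
        return {c: int(k) for c, k in zip(names, rng.poisson(rate, size=n)) if k}
    return OntologyGraph(
        classes=frozenset(names),
        subclass_edges=tuple(edges),
        object_property_assertions=tally(0.8),
        datatype_property_assertions=tally(0.5),
        restrictions=tally(0.6),
        individuals=tally(0.4),
        annotation_assertions=tally(0.7),
    )
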