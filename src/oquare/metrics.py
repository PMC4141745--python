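"""The twelve structural/axiomatic ontology quality metrics.

All metrics are ratios of asserted-axiom counts over the class set, except
DITOnto (an integer depth).  The roster, with its object-oriented software
metric ancestry:

======== ==============================================================
LCOMOnto mean root-to-leaf path length over all distinct paths
WMCOnto  (property assertions + subclass edges) per class
DITOnto  length in edges of the longest root-to-leaf path
NACOnto  mean number of direct named superclasses per leaf class
NOCOnto  subclass edges per class not attached directly under the root
RFCOnto  property assertions directly accessible from a class, per class
NOMOnto  property assertions per class
PROnto   property assertions / (subclass edges + property assertions)
AROnto   restrictions per class
INROnto  subclass edges per class
CROnto   individual class-membership assertions per class
ANOnto   class annotation assertions per class
======== ==============================================================

Any metric whose denominator is zero is reported as 0 and flagged in
``MetricVector.degenerate`` so the scoring layer can keep pipelines total
while preserving auditability.
"""

from __future__ import annotations

from dataclasses import dataclass

from .owl_model import OntologyGraph, path_length, root_to_leaf_paths

#: Canonical metric names, in roster order.
METRIC_NAMES: tuple[str, ...] = (
    "LCOMOnto",
    "WMCOnto",
    "DITOnto",
    "NACOnto",
    "NOCOnto",
    "RFCOnto",
    "NOMOnto",
    "PROnto",
    "AROnto",
    "INROnto",
    "CROnto",
    "ANOnto",
)


@dataclass(frozen=True)
class MetricVector:
    """Values of the twelve metrics for one ontology."""

    LCOMOnto: float
    WMCOnto: float
    DITOnto: int
    NACOnto: float
    NOCOnto: float
    RFCOnto: float
    NOMOnto: float
    PROnto: float
    AROnto: float
    INROnto: float
    CROnto: float
    ANOnto: float
    degenerate: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def __getitem__(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def _ancestor_closure(g: OntologyGraph) -> dict[str, set[str]]:
    parents: dict[str, list[str]] = {}
    for child, parent in g.subclass_edges:
        parents.setdefault(child, []).append(parent)
    memo: dict[str, set[str]] = {}

    def anc(c: str) -> set[str]:
        if c not in memo:
            memo[c] = set()  # cycle guard; graph is checked acyclic upstream
            out: set[str] = set()
            for p in parents.get(c, ()):
                out.add(p)
                out |= anc(p)
            memo[c] = out
        return memo[c]

    return {c: anc(c) for c in g.classes}


def compute_metrics(g: OntologyGraph, rfc_inherited: bool = False) -> MetricVector:
    """Compute the metric vector for one ontology.

    Parameters
    ----------
    g
        Parsed asserted ontology content.  The subclass hierarchy must be
        acyclic (a cycle raises :class:`~oquare.owl_model.CyclicHierarchyError`).
    rfc_inherited
        If True, RFCOnto counts property assertions reachable from each
        class through its ancestors as well as its own; the default counts
        only assertions directly attached to the class.
    """
    n = g.n_classes
    degenerate: set[str] = set()
    if n == 0:
        return MetricVector(
            LCOMOnto=0.0, WMCOnto=0.0, DITOnto=0, NACOnto=0.0, NOCOnto=0.0,
            RFCOnto=0.0, NOMOnto=0.0, PROnto=0.0, AROnto=0.0, INROnto=0.0,
            CROnto=0.0, ANOnto=0.0, degenerate=frozenset(METRIC_NAMES),
        )

    paths = root_to_leaf_paths(g)  # nonempty for any acyclic graph with >=1 class
    lengths = [path_length(p) for p in paths]
    edges = g.n_subclass_edges
    props = g.n_object_property_assertions + g.n_datatype_property_assertions

    lcom = sum(lengths) / len(paths)
    dit = max(lengths)

    has_child = {parent for _, parent in g.subclass_edges}
    parent_count: dict[str, int] = {}
    for child, _ in g.subclass_edges:
        parent_count[child] = parent_count.get(child, 0) + 1
    leaves = sorted(c for c in g.classes if c not in has_child)
    # orphan leaves count their implicit root attachment as one superclass
    nac = sum(parent_count.get(leaf, 0) or 1 for leaf in leaves) / len(leaves)

    non_top = sum(1 for c in g.classes if parent_count.get(c, 0) > 0)
    if non_top:
        noc = edges / non_top
    else:
        noc = 0.0
        degenerate.add("NOCOnto")

    if rfc_inherited:
        ancestors = _ancestor_closure(g)
        own = {
            c: g.object_property_assertions.get(c, 0) + g.datatype_property_assertions.get(c, 0)
            for c in g.classes
        }
        rfc = sum(own[c] + sum(own[a] for a in ancestors[c]) for c in g.classes) / n
    else:
        rfc = props / n

    if edges + props:
        pro = props / (edges + props)
    else:
        pro = 0.0
        degenerate.add("PROnto")

    return MetricVector(
        LCOMOnto=lcom,
        WMCOnto=(props + edges) / n,
        DITOnto=dit,
        NACOnto=nac,
        NOCOnto=noc,
        RFCOnto=rfc,
        NOMOnto=props / n,
        PROnto=pro,
        AROnto=g.n_restrictions / n,
        INROnto=edges / n,
        CROnto=g.n_individuals / n,
        ANOnto=g.n_annotation_assertions / n,
        degenerate=frozenset(degenerate),
    )
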