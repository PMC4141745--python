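"""Random OWL ontologies and labeled trial cohorts.

The cohort emulator mirrors the design of a crossed randomized controlled
trial of guideline-based ontology-engineering training: 24 students, six
modeling topics (PRO, IMM, CME, INF, CLO, SPA) with two tasks each, so each
student produces 12 ontologies (288 files in total).  Group A students are
trained on PRO, IMM and CLO; group B on CME, INF and SPA — every ontology is
therefore labeled trained or untrained depending on whether its author was
trained on its topic.  Expert gold-standard ontologies accompany each task.

Balanced subsampling retains an equal number of trained and untrained files
per task (default 9+9 of 24, i.e. 216 of 288) while guaranteeing that every
student remains represented in the retained set.

Ontology structure is a random rooted DAG grown by preferential-free random
attachment: class *i* picks a uniformly random parent among already-created
classes whose depth allows it, or attaches at the root.  Axiom densities
(properties, restrictions, annotations, individuals) are Poisson/Bernoulli
per class.  One RNG stream is derived per (student, topic, task) from the
master seed, so subsetting a cohort never perturbs unrelated draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .owl_model import OntologyGraph

#: The six modeling topics, in design order.
TOPICS: tuple[str, ...] = ("PRO", "IMM", "CME", "INF", "CLO", "SPA")

#: Topics on which group A received specific training (group B: the rest).
GROUP_A_TOPICS: frozenset[str] = frozenset({"PRO", "IMM", "CLO"})

ARMS: tuple[str, str] = ("untrained", "trained")


class GeneratorConfigError(ValueError):
    """Raised for an infeasible or invalid generator/cohort configuration."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one random-ontology draw.

    Rates are per-class expectations; probabilities are per-class Bernoulli
    parameters.  Generation under a fixed ``seed`` is reproducible
    bit-for-bit at the :class:`~oquare.owl_model.OntologyGraph` level.
    """

    n_classes: int = 30
    max_depth: int = 6
    root_attach_prob: float = 0.15  # branching: chance a new class starts a new top-level branch
    multi_parent_prob: float = 0.15
    property_density: float = 1.0  # expected property-domain assertions per class (obj+dt)
    restriction_density: float = 0.5
    annotation_coverage: float = 0.03  # fraction of classes carrying an annotation
    individuals_per_class: float = 0.2
    seed: int | None = None

    def validate(self) -> None:
        if self.n_classes < 0:
            raise GeneratorConfigError("n_classes must be >= 0")
        if self.n_classes > 0 and self.max_depth < 1:
            raise GeneratorConfigError("max_depth must be >= 1 when n_classes > 0")
        for name in ("root_attach_prob", "multi_parent_prob", "annotation_coverage"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise GeneratorConfigError(f"{name} must lie in [0, 1], got {p}")
        for name in ("property_density", "restriction_density", "individuals_per_class"):
            if getattr(self, name) < 0:
                raise GeneratorConfigError(f"{name} must be >= 0")

    def shifted(self, shifts: Mapping[str, float]) -> "GeneratorSpec":
        """Apply additive parameter shifts, clipping probabilities to [0, 1]."""
        updates = {}
        for name, delta in shifts.items():
            value = getattr(self, name) + delta
            if name in ("root_attach_prob", "multi_parent_prob", "annotation_coverage"):
                value = min(1.0, max(0.0, value))
            else:
                value = max(0.0, value)
            updates[name] = value
        return dataclasses.replace(self, **updates)


def generate_ontology(
    spec: GeneratorSpec,
    rng: np.random.Generator | None = None,
    iri: str = "http://example.org/synthetic",
) -> OntologyGraph:
    """Draw one random ontology honouring ``spec``.

    The class graph is acyclic by construction (parents are always
    earlier-created classes) and the exact class count is honoured; axiom
    densities hold in expectation.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_classes
    names = [f"{iri}#C{i:04d}" for i in range(n)]

    depth: dict[str, int] = {}
    edges: set[tuple[str, str]] = set()
    for i, cls in enumerate(names):
        eligible = [c for c in names[:i] if depth[c] < spec.max_depth]
        if i == 0 or not eligible or rng.random() < spec.root_attach_prob:
            depth[cls] = 1
            continue
        parent = eligible[rng.integers(len(eligible))]
        parents = [parent]
        if len(eligible) > 1 and rng.random() < spec.multi_parent_prob:
            second = eligible[rng.integers(len(eligible))]
            if second != parent:
                parents.append(second)
        for p in parents:
            edges.add((cls, p))
        depth[cls] = 1 + max(depth[p] for p in parents)

    obj_tally: dict[str, int] = {}
    dt_tally: dict[str, int] = {}
    restr_tally: dict[str, int] = {}
    ann_tally: dict[str, int] = {}
    ind_tally: dict[str, int] = {}
    for cls in names:
        n_obj = int(rng.poisson(spec.property_density / 2))
        n_dt = int(rng.poisson(spec.property_density / 2))
        n_restr = int(rng.poisson(spec.restriction_density))
        # each restriction carries an onProperty occurrence: 80% object, 20% datatype
        restr_obj = int(np.sum(rng.random(n_restr) < 0.8)) if n_restr else 0
        if n_obj + restr_obj:
            obj_tally[cls] = n_obj + restr_obj
        if n_dt + (n_restr - restr_obj):
            dt_tally[cls] = n_dt + (n_restr - restr_obj)
        if n_restr:
            restr_tally[cls] = n_restr
        if rng.random() < spec.annotation_coverage:
            ann_tally[cls] = 1
        n_ind = int(rng.poisson(spec.individuals_per_class))
        if n_ind:
            ind_tally[cls] = n_ind

    return OntologyGraph(
        classes=frozenset(names),
        subclass_edges=tuple(edges),
        thing_children=frozenset(),
        object_property_assertions=obj_tally,
        datatype_property_assertions=dt_tally,
        restrictions=restr_tally,
        individuals=ind_tally,
        annotation_assertions=ann_tally,
        ontology_iri=iri,
    )


def write_owl(g: OntologyGraph, path: str | Path | None = None) -> bytes:
    """Serialize an :class:`OntologyGraph` as OWL 2 RDF/XML.

    Re-parsing the emitted document reproduces ``g``'s counts exactly:
    ``parse_owl(write_owl(g)).counts() == g.counts()``.  Property usages are
    realized as restrictions first (up to the class's restriction tally) and
    the remainder as ``rdfs:domain`` declarations on fresh properties.

    The document is emitted directly (classes in sorted order, properties in
    creation order) so the bytes are a deterministic function of ``g``.
    """
    from xml.sax.saxutils import escape, quoteattr

    base = g.ontology_iri or "http://example.org/ontology"
    parents_of: dict[str, list[str]] = {}
    for child, parent in g.subclass_edges:
        parents_of.setdefault(child, []).append(parent)

    out: list[str] = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"',
        '         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"',
        '         xmlns:owl="http://www.w3.org/2002/07/owl#">',
        f"  <owl:Ontology rdf:about={quoteattr(base)}/>",
    ]
    prop_decls: list[str] = []
    individuals: list[str] = []
    prop_counter = 0

    def fresh(kind: str) -> str:
        nonlocal prop_counter
        prop_counter += 1
        return f"{base}#{kind}{prop_counter:05d}"

    for cls in sorted(g.classes):
        out.append(f"  <owl:Class rdf:about={quoteattr(cls)}>")
        if cls in g.thing_children:
            out.append('    <rdfs:subClassOf rdf:resource="http://www.w3.org/2002/07/owl#Thing"/>')
        for parent in sorted(parents_of.get(cls, ())):
            out.append(f"    <rdfs:subClassOf rdf:resource={quoteattr(parent)}/>")

        n_obj = g.object_property_assertions.get(cls, 0)
        n_dt = g.datatype_property_assertions.get(cls, 0)
        n_restr = g.restrictions.get(cls, 0)
        restr_obj = min(n_restr, n_obj)
        restr_dt = min(n_restr - restr_obj, n_dt)
        fillers = [("ObjectProperty", "http://www.w3.org/2002/07/owl#Thing", "op", restr_obj),
                   ("DatatypeProperty", "http://www.w3.org/2001/XMLSchema#string", "dp", restr_dt)]
        for kind, filler, tag, count in fillers:
            for _ in range(count):
                p = fresh(tag)
                prop_decls.append(f"  <owl:{kind} rdf:about={quoteattr(p)}/>")
                out += [
                    "    <rdfs:subClassOf>",
                    "      <owl:Restriction>",
                    f"        <owl:onProperty rdf:resource={quoteattr(p)}/>",
                    f"        <owl:someValuesFrom rdf:resource={quoteattr(filler)}/>",
                    "      </owl:Restriction>",
                    "    </rdfs:subClassOf>",
                ]
        # restrictions beyond the property tallies (hand-built graphs only):
        # emit property-less restriction nodes so the count round-trips
        for _ in range(n_restr - restr_obj - restr_dt):
            out += ["    <rdfs:subClassOf>", "      <owl:Restriction/>", "    </rdfs:subClassOf>"]
        for kind, tag, count in (
            ("ObjectProperty", "op", n_obj - restr_obj),
            ("DatatypeProperty", "dp", n_dt - restr_dt),
        ):
            for _ in range(count):
                p = fresh(tag)
                prop_decls.append(
                    f"  <owl:{kind} rdf:about={quoteattr(p)}>"
                    f"<rdfs:domain rdf:resource={quoteattr(cls)}/></owl:{kind}>"
                )
        for k in range(g.annotation_assertions.get(cls, 0)):
            out.append(f"    <rdfs:comment>annotation {k}</rdfs:comment>")
        out.append("  </owl:Class>")
        for k in range(g.individuals.get(cls, 0)):
            individuals.append(
                f"  <owl:NamedIndividual rdf:about={quoteattr(cls + f'_i{k:03d}')}>"
                f"<rdf:type rdf:resource={quoteattr(cls)}/></owl:NamedIndividual>"
            )

    out += prop_decls + individuals + ["</rdf:RDF>", ""]
    data = "\n".join(out).encode("utf-8")
    if path is not None:
        Path(path).write_bytes(data)
    return data


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic trial cohort.

    ``effect_profile`` maps each topic to additive :class:`GeneratorSpec`
    parameter shifts applied to the *trained* arm for that topic.  Defaults
    emulate the reported training signature: trained students assert less
    multiple parenthood and annotate slightly more classes, while still
    annotating far fewer classes than the gold standards (whose coverage is
    near-total).
    """

    students: int = 24
    tasks_per_topic: int = 2
    topics: tuple[str, ...] = TOPICS
    base_spec: GeneratorSpec = field(default_factory=GeneratorSpec)
    topic_spec_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    effect_profile: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            topic: {"multi_parent_prob": -0.10, "annotation_coverage": +0.05}
            for topic in TOPICS
        }
    )
    gold_spec: GeneratorSpec = field(
        default_factory=lambda: GeneratorSpec(
            multi_parent_prob=0.02, annotation_coverage=0.95, restriction_density=0.8
        )
    )

    def validate(self) -> None:
        if self.students < 2 or self.students % 2:
            raise GeneratorConfigError("students must be an even number >= 2")
        if self.tasks_per_topic < 1:
            raise GeneratorConfigError("tasks_per_topic must be >= 1")
        if len(set(self.topics)) != len(self.topics):
            raise GeneratorConfigError("topics must be distinct")
        self.base_spec.validate()
        self.gold_spec.validate()

    def spec_for(self, topic: str, arm: str) -> GeneratorSpec:
        spec = self.base_spec
        if topic in self.topic_spec_overrides:
            spec = spec.shifted(self.topic_spec_overrides[topic])
        if arm == "trained":
            spec = spec.shifted(self.effect_profile.get(topic, {}))
        return spec

    def arm_of(self, student: int, topic: str) -> str:
        """Group A = first half of the student roster, trained on PRO/IMM/CLO."""
        group_a = student < self.students // 2
        trained = (topic in GROUP_A_TOPICS) == group_a
        return "trained" if trained else "untrained"


@dataclass(frozen=True)
class CohortRecord:
    """One labeled student ontology."""

    ontology_id: str
    student: int
    topic: str
    task: int
    arm: str
    graph: OntologyGraph


@dataclass(frozen=True)
class Cohort:
    """A labeled set of student ontologies plus per-(topic, task) golds."""

    design: CohortDesign
    records: tuple[CohortRecord, ...]
    golds: Mapping[tuple[str, int], OntologyGraph]
    seed: int

    def __len__(self) -> int:
        return len(self.records)

    @property
    def students_present(self) -> frozenset[int]:
        return frozenset(r.student for r in self.records)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def generate_cohort(design: CohortDesign | None = None, seed: int = 0) -> Cohort:
    """Generate the full labeled cohort (default: 24 x 6 x 2 = 288 files).

    Each (student, topic, task) cell draws from its own RNG stream derived
    from ``seed``, so any subset of the cohort is reproducible on its own.
    Gold standards (one per topic x task) use dedicated streams.
    """
    if design is None:
        design = CohortDesign()
    design.validate()
    records = []
    for student in range(design.students):
        for t_idx, topic in enumerate(design.topics):
            arm = design.arm_of(student, topic)
            spec = design.spec_for(topic, arm)
            for task in range(design.tasks_per_topic):
                rng = _stream(seed, 0, student, t_idx, task)
                oid = f"s{student:02d}_{topic}_t{task}"
                graph = generate_ontology(
                    spec, rng=rng, iri=f"http://example.org/cohort/{oid}"
                )
                records.append(
                    CohortRecord(ontology_id=oid, student=student, topic=topic, task=task, arm=arm, graph=graph)
                )
    golds = {}
    for t_idx, topic in enumerate(design.topics):
        for task in range(design.tasks_per_topic):
            rng = _stream(seed, 1, t_idx, task)
            golds[(topic, task)] = generate_ontology(
                design.gold_spec, rng=rng, iri=f"http://example.org/gold/{topic}_t{task}"
            )
    return Cohort(design=design, records=tuple(records), golds=golds, seed=seed)


def sample_balanced(cohort: Cohort, keep_per_task: int = 18, seed: int = 0) -> Cohort:
    """Retain ``keep_per_task`` files per (topic, task), arm-balanced.

    Per (topic, task) exactly ``keep_per_task // 2`` trained and as many
    untrained files are kept, and globally every student keeps at least one
    file (resampled until satisfied; the failure probability per attempt is
    negligible at the default design).
    """
    design = cohort.design
    if keep_per_task > design.students:
        raise GeneratorConfigError("keep_per_task cannot exceed the number of students")
    if keep_per_task % 2:
        raise GeneratorConfigError("keep_per_task must be even to balance two arms")
    if keep_per_task == design.students:
        return cohort
    per_arm = keep_per_task // 2
    by_cell: dict[tuple[str, int, str], list[CohortRecord]] = {}
    for rec in cohort.records:
        by_cell.setdefault((rec.topic, rec.task, rec.arm), []).append(rec)
    for (topic, task, arm), recs in by_cell.items():
        if len(recs) < per_arm:
            raise GeneratorConfigError(
                f"cell ({topic}, task {task}, {arm}) has {len(recs)} files < {per_arm} requested"
            )

    all_students = cohort.students_present
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    for _attempt in range(1000):
        kept: list[CohortRecord] = []
        for key in sorted(by_cell):
            recs = sorted(by_cell[key], key=lambda r: r.ontology_id)
            idx = rng.choice(len(recs), size=per_arm, replace=False)
            kept.extend(recs[i] for i in sorted(idx))
        if frozenset(r.student for r in kept) == all_students:
            kept.sort(key=lambda r: r.ontology_id)
            return Cohort(design=design, records=tuple(kept), golds=cohort.golds, seed=cohort.seed)
    raise GeneratorConfigError("could not satisfy the all-students constraint")  # pragma: no cover


def write_cohort(cohort: Cohort, out_dir: str | Path) -> "Path":
    """Write a cohort as OWL files plus a manifest CSV; returns the manifest path.

    Layout: ``<out>/owl/<ontology_id>.owl``, ``<out>/gold/<topic>_t<task>.owl``,
    ``<out>/manifest.csv`` with columns file, student, topic, task, arm.
    """
    out = Path(out_dir)
    (out / "owl").mkdir(parents=True, exist_ok=True)
    (out / "gold").mkdir(parents=True, exist_ok=True)
    lines = ["file,student,topic,task,arm"]
    for rec in cohort.records:
        rel = f"owl/{rec.ontology_id}.owl"
        write_owl(rec.graph, out / rel)
        lines.append(f"{rel},{rec.student},{rec.topic},{rec.task},{rec.arm}")
    for (topic, task), graph in sorted(cohort.golds.items()):
        write_owl(graph, out / "gold" / f"{topic}_t{task}.owl")
    manifest = out / "manifest.csv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
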