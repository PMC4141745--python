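# Methods

This note records the models implemented, the conventions and constants the
package had to fix where the framework leaves them open, and what the
synthetic cohorts do and do not establish about real ontology collections.

## Assertion-level ontology model

All metrics are defined over *asserted* axioms; no reasoner is involved and
`owl:imports` are never resolved. This keeps counts a property of the
document itself: student-built artifacts are scored as written, and a
serializer's habits (asserting `owl:Thing` parenthood, duplicating axioms)
cannot move a denominator. Concretely:

* Named classes only; anonymous class expressions are never classes.
* Subclass edges are distinct asserted axioms between named classes.
  `A ⊑ owl:Thing` assertions are recorded but excluded from edge totals;
  classes with no asserted named superclass are implicitly rooted at
  `owl:Thing` for path computations only. Exact duplicates count once.
* A property usage is an `rdfs:domain` declaration on a class or an
  `owl:onProperty` occurrence inside a restriction attached to a class.
  Restrictions are counted once per occurrence, inclusively (existential,
  universal, cardinality, hasValue), whether attached via subclass or
  equivalent-class axioms and whether direct or operands of
  intersection/union/complement expressions. Equivalence contributes
  restrictions but never subclass edges. Properties of undeclared type
  found in restrictions are treated as object properties.
* Individuals are class-membership assertions; annotations are triples on a
  class whose predicate is a declared `owl:AnnotationProperty` or one of
  the built-ins (`rdfs:label`, `rdfs:comment`, `rdfs:seeAlso`,
  `rdfs:isDefinedBy`, `owl:versionInfo`, `owl:deprecated`).

Parsing uses rdflib; serialization is emitted directly by `write_owl` so
that output bytes are a deterministic function of the graph (rdflib's XML
serializers are not byte-stable run to run). Round-trip identity of all
counts is enforced by tests over randomized generator settings.

## Metric conventions

The twelve metrics follow their standard definitions; where a definition is
ambiguous the package fixes it as follows and exposes a switch when a
defensible alternative exists.

* **LCOMOnto** is the *mean* root-to-leaf path length over all distinct
  directed paths (so LCOMOnto ≤ DITOnto always). Path length counts edges
  including the root attachment: a single orphan class has depth 1, not 0.
* **NACOnto** averages direct named superclasses over leaf classes, with
  orphan leaves counting their root attachment as one superclass.
* **NOCOnto** uses the subclass-edge total over the classes not attached
  directly under the root (i.e. classes with at least one named
  superclass). The metric's customary name ("number of children") and its
  per-superclass wording disagree; both orientations share the same edge
  multiset, so only the denominator needed fixing, and the literal wording
  won.
* **RFCOnto** counts property assertions *directly* attached to a class
  (domain or restriction on that class), averaged per class;
  `rfc_inherited=True` extends access through ancestors. Under the default
  it numerically coincides with NOMOnto because every counted property
  usage is attached to exactly one class — the two metrics diverge only in
  the inherited variant.
* Any metric with a zero denominator reports 0 and is flagged degenerate;
  the scoring layer maps degenerate metrics to score 1 rather than
  aborting, keeping cohort pipelines total while preserving auditability.

## Quality model

The aggregation mechanism is fixed: four strictly increasing cut points per
metric split its range into five bands (half-open on the upper side, so a
value exactly at cut point `b3` of a higher-better metric scores 4); metric
scores are integers 1–5; subcharacteristic and characteristic scores are
weighted means and therefore real-valued in [1, 5]. Weighted means are
clamped into the [min, max] of their inputs to remove floating-point drift
at the scale boundaries.

The *constants* of the default model — the band values, the 12×29 mapping
matrix, the 29×7 grouping — are a reconstruction: the framework publishes
the mechanism but not a canonical constant set. The reconstruction honours
every documented anchor (ANOnto → Knowledge Reuse, Redundancy, Controlled
Vocabulary; NOCOnto/NACOnto → Tangledness; LCOMOnto → Cohesion and
Modularity), assigns the complexity/coupling-style metrics (LCOMOnto,
WMCOnto, DITOnto, NOCOnto, RFCOnto, NOMOnto) lower-is-better directions and
the richness-style metrics (ANOnto, AROnto, CROnto, INROnto, PROnto,
NACOnto) higher-is-better, and uses equal weights within each aggregation
level. Seven characteristics are modeled; Transferability maps to
Adaptability + Replaceability (its portability content), shared with
Compatibility — the model is an explicit many-to-many weighted mapping, so
sharing is well-defined. Every constant is overridable by loading a YAML
file of the same shape; correctness claims attach to the mechanism, which
is what the test suite checks.

## Synthetic cohorts

The generator emulates the artifact structure of a crossed post-test-only
trial: 24 students, six topics with two tasks each, each student trained on
exactly three topics (group A: PRO, IMM, CLO; group B: CME, INF, SPA), 288
ontologies in total, two gold standards per topic. Balanced subsampling
keeps 18 of 24 files per task (9 per arm) and resamples until every student
remains represented, the only stated global constraint.

Ontology structure is a random rooted DAG: each new class attaches to a
uniformly chosen earlier class whose depth permits it (`max_depth` 6 by
default), starts a new top branch with probability 0.15, and acquires a
second parent with probability `multi_parent_prob`. Axiom densities are
Poisson per class (properties 1.0, restrictions 0.5, individuals 0.2) and
annotation presence Bernoulli per class. Default class count is 30 —
task-scale teaching ontologies, not production terminologies.

Effect defaults encode the trial's reported training signature
directionally: students annotate under 10% of classes (baseline coverage
0.03, trained +0.05) while gold standards annotate nearly all (0.95), and
trained students assert less multiple parenthood (0.15 → 0.05). The
magnitudes are free parameters of the design object; nothing downstream
depends on them beyond direction. One RNG stream is derived per (student,
topic, task) from the master seed, so any subset of a cohort reproduces
bit-for-bit on its own.

What passing tests on these cohorts shows: the pipeline's arithmetic,
balance guarantees, calibration and recovery properties. What they do not
show: anything about the metric distributions of human-built OWL artifacts
— real ontologies have correlated axiom patterns, heterogeneous sizes and
linguistically meaningful annotation behaviour that independent Poisson
draws do not emulate.

## Statistical pipeline

* **ANOVA.** Two-way fixed-effects training × topic with interaction,
  computed in closed form, which is exact for the balanced design
  (SS_training + SS_topic + SS_interaction + SS_residual = SS_total to
  1e-8 relative, verified on every run); unbalanced tables are rejected
  outright rather than reinterpreted through Type-II/III sums of squares,
  because the design argument for the F statistic rests on equal cell
  sizes. The implementation is cross-checked against statsmodels'
  `anova_lm` in the test suite. Zero-variance tables report p = 1; zero
  residual variance with non-zero effect reports p = 0.
* **t-tests.** Pooled-variance by default (balanced design), Welch by
  flag; per-arm means carry t-based 95% confidence intervals. Identical
  constant arms report t = 0, p = 1. No multiple-testing correction is
  applied by default (matching the raw-significance reporting convention);
  the study command gates t-tests on interaction significance at a
  configurable α.
* **Distances.** `D_k = |G − x̄_k|` per (subcharacteristic, topic), with
  the gold score taken as the mean over that topic's gold ontologies. The
  transformation is pluggable should a different distance be wanted.
* **Clustering.** Ward linkage on Euclidean row distances (scipy), cut at
  k = 4; K-means (scikit-learn, 10 restarts, seeded) reports the
  percentage of total variance explained between groups and the per-group
  within-group shares.
* **PCA.** Column-centered SVD (covariance PCA) by default — the matrices
  are already on a common score scale — with a correlation-PCA flag.
  Component signs are fixed by making each component's largest-magnitude
  loading positive. Explained variances sum to 100%; a zero-variance
  matrix is defined to return zero scores and the input order.

Calibration suites run the interaction test and the t-test on 1000 null
tables (type-I error within 0.05 ± 0.02) and verify ≥80% power for a
1.0-score single-topic trained-arm shift at σ = 0.5 and 9 observations per
cell — the trial's own cell size after subsampling when analysed per task.
Simulated tables for calibration come from a Gaussian cell-means model
rather than full ontology generation, which keeps a thousand replicates in
seconds without changing what is being calibrated.

## Problem sizes

Default test and acceptance workloads: 500-ontology scoring batteries
(1–45 classes each), 200-graph oracle comparisons (≤50 classes), 1000-table
calibration runs, 100-seed round-trips. These sizes give Monte-Carlo
standard errors well inside the asserted bands (e.g. ±0.007 on a 0.05
rejection rate at 1000 replicates) while a full suite run stays in the tens
of seconds.

## Known limitations

* The default band constants and mapping matrix are reconstructions;
  absolute scores from two different constant sets are not comparable, and
  any empirical result tied to the original constants is out of scope here.
* RDF/XML is the contracted dialect; other OWL serializations parse only
  insofar as rdflib maps them to the same triples (not tested, not
  promised). OBO, SPARQL and DL reasoning are non-goals.
* The parser's restriction walk descends intersection/union/complement
  operands but not arbitrarily nested class expressions inside restriction
  fillers; the generator never emits such nesting.
* Path enumeration is exhaustive; on densely multi-parented hierarchies
  the number of distinct root-to-leaf paths can grow combinatorially.
  At the package's intended scale (teaching-task ontologies, tens of
  classes, sparse multiple parenthood) this is immaterial.
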