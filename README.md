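# oquare

Quality scoring for OWL 2 ontologies, plus the statistical machinery to use
those scores as the outcome parameter of a randomized controlled trial of
ontology-engineering training.

## What it does

Ontology evaluation frameworks in the SQuaRE/ISO 25000 tradition grade an
ontology on a hierarchy *metrics → subcharacteristics → characteristics*.
This package implements that pipeline end to end:

* **Twelve structural/axiomatic metrics** computed on the *asserted* content
  of an OWL 2 ontology (RDF/XML): LCOMOnto, WMCOnto, DITOnto, NACOnto,
  NOCOnto, RFCOnto, NOMOnto, PROnto, AROnto, INROnto, CROnto, ANOnto.
  They are ratios of assertion-occurrence counts — e.g. INROnto is subclass
  axioms per class, ANOnto annotation assertions per class, DITOnto the
  longest root-to-leaf path in edges. Counts refer to assertions, not to
  declared entities.
* **1–5 band scoring and weighted aggregation.** Each metric value is
  mapped onto the ordinal scale 1 ("not acceptable") … 3 ("minimally
  acceptable") … 5 ("exceeds the requirements") via four threshold cut
  points; subcharacteristic scores are weighted means of metric scores and
  characteristic scores weighted means of subcharacteristic scores. The
  default quality model ships 29 subcharacteristics and 7 characteristics
  and is fully overridable from YAML.
* **A synthetic trial-cohort generator.** 24 students × 6 topics (PRO, IMM,
  CME, INF, CLO, SPA) × 2 tasks = 288 random ontologies in a crossed design
  (group A trained on PRO/IMM/CLO, group B on CME/INF/SPA), plus expert
  gold-standard ontologies per task, plus arm-balanced subsampling
  (216 of 288 retained, 9 trained + 9 untrained per task, every student
  still represented).
* **The trial's outcome analysis.** Per subcharacteristic: balanced two-way
  ANOVA (training × topic, with interaction, exact closed-form
  decomposition), per-topic two-sample t-tests with per-arm confidence
  intervals, absolute mean distances to the gold standard arranged as two
  29×6 matrices D1 (untrained) and D2 (trained), Ward and K-means clustering
  of the subcharacteristic rows, and a centered PCA ordering them.

The formula at the core of the distance analysis is
`D_k[s, t] = |G(s, t) − x̄_k(s, t)|`, where `G` is the gold-standard score of
subcharacteristic `s` on topic `t` and `x̄₁`, `x̄₂` are the untrained/trained
arm means.

## Worked example

```python
from oquare import parse_owl, evaluate_ontology

g = parse_owl("tests/data/chain3.owl")   # classes A, B, C with B⊑A, C⊑B
card = evaluate_ontology(g)              # default quality model

mv = card.metric_values
print(mv.DITOnto, mv.LCOMOnto, round(mv.INROnto, 3))
# 3 3.0 0.667    — one path Thing→A→B→C of length 3; 2 edges / 3 classes

print(card.subcharacteristic_scores["Cohesion"])     # 4.0
print(card.subcharacteristic_scores["Redundancy"])   # 1.0
print(round(card.characteristic_scores["Structural"], 3))  # 2.083
```

The chain has a shallow, untangled hierarchy (good Cohesion: LCOMOnto of 3
scores 4 under the default lower-is-better bands) but no annotations at all,
so ANOnto = 0 scores 1 and drags Redundancy, Controlled Vocabulary and with
them the Structural characteristic down — exactly the annotation-poverty
signature the score hierarchy is designed to expose.

A full synthetic trial from the shell:

```bash
oquare simulate --seed 7 --keep-per-task 18 --out cohort/   # 288 OWL files + manifests
oquare study --cohort cohort/ --seed 7 --out results/       # ANOVA, t-tests, D1/D2, clusters, PCA
oquare evaluate cohort/owl/s00_PRO_t0.owl --out cards/      # single-file scorecards
```

## Layout

```
src/oquare/owl_model.py   RDF/XML parsing → assertion-level OntologyGraph
src/oquare/metrics.py     the twelve metrics
src/oquare/scoring.py     band scoring + weighted aggregation, YAML config
src/oquare/data/          default quality model (29 subchars, 7 chars)
src/oquare/synthetic.py   random ontologies, trial cohorts, OWL writer
src/oquare/pipeline.py    ANOVA, t-tests, gold distances, clustering, PCA
src/oquare/cli.py         oquare evaluate | simulate | study
docs/methods.md           models, conventions, parameter choices, limits
```
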