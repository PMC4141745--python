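"""Parsing and path enumeration on the asserted class hierarchy."""

import numpy as np
import pytest

from oquare.owl_model import (
    THING,
    CyclicHierarchyError,
    OntologyGraph,
    OWLParseError,
    parse_owl,
    path_length,
    root_to_leaf_paths,
)

from .oracles import brute_force_paths, random_dag_graph

PREFIX = "http://example.org/chain3#"

MINIMAL_DOC = b"""<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:owl="http://www.w3.org/2002/07/owl#">
  <owl:Class rdf:about="http://example.org/min#A"/>
</rdf:RDF>
"""


class TestParseOwl:
    def test_single_class_document(self):
        g = parse_owl(MINIMAL_DOC)
        assert g.classes == {"http://example.org/min#A"}
        assert g.counts() == {
            "classes": 1,
            "subclass_edges": 0,
            "thing_children": 0,
            "object_property_assertions": 0,
            "datatype_property_assertions": 0,
            "restrictions": 0,
            "individuals": 0,
            "annotation_assertions": 0,
        }

    def test_chain3_fixture(self, chain3_path):
        g = parse_owl(chain3_path)
        assert g.classes == {PREFIX + c for c in "ABC"}
        assert set(g.subclass_edges) == {(PREFIX + "B", PREFIX + "A"), (PREFIX + "C", PREFIX + "B")}
        assert g.ontology_iri == "http://example.org/chain3"

    def test_truncated_stream_raises(self):
        with pytest.raises(OWLParseError):
            parse_owl(MINIMAL_DOC[:40])

    def test_empty_document_is_valid_empty_graph(self):
        doc = b"""<?xml version="1.0"?>
        <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"/>"""
        g = parse_owl(doc)
        assert g.n_classes == 0

    def test_deterministic(self, chain3_path):
        data = chain3_path.read_bytes()
        assert parse_owl(data) == parse_owl(data)

    def test_thing_edges_recorded_but_not_subclass_edges(self):
        doc = b"""<?xml version="1.0"?>
        <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
                 xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
                 xmlns:owl="http://www.w3.org/2002/07/owl#">
          <owl:Class rdf:about="http://x.org#A">
            <rdfs:subClassOf rdf:resource="http://www.w3.org/2002/07/owl#Thing"/>
          </owl:Class>
        </rdf:RDF>"""
        g = parse_owl(doc)
        assert g.subclass_edges == ()
        assert g.thing_children == {"http://x.org#A"}

    def test_duplicate_axioms_count_once(self):
        doc = b"""<?xml version="1.0"?>
        <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
                 xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
                 xmlns:owl="http://www.w3.org/2002/07/owl#">
          <owl:Class rdf:about="http://x.org#B">
            <rdfs:subClassOf rdf:resource="http://x.org#A"/>
            <rdfs:subClassOf rdf:resource="http://x.org#A"/>
          </owl:Class>
        </rdf:RDF>"""
        g = parse_owl(doc)
        assert g.subclass_edges == (("http://x.org#B", "http://x.org#A"),)

    def test_restriction_and_property_usage_counting(self):
        # A has an existential restriction on object property p (via subClassOf)
        # and an equivalent-class intersection carrying a second restriction on
        # datatype property q; q also has a domain declaration on A.
        doc = b"""<?xml version="1.0"?>
        <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
                 xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
                 xmlns:owl="http://www.w3.org/2002/07/owl#">
          <owl:ObjectProperty rdf:about="http://x.org#p"/>
          <owl:DatatypeProperty rdf:about="http://x.org#q">
            <rdfs:domain rdf:resource="http://x.org#A"/>
          </owl:DatatypeProperty>
          <owl:Class rdf:about="http://x.org#B"/>
          <owl:Class rdf:about="http://x.org#A">
            <rdfs:subClassOf>
              <owl:Restriction>
                <owl:onProperty rdf:resource="http://x.org#p"/>
                <owl:someValuesFrom rdf:resource="http://x.org#B"/>
              </owl:Restriction>
            </rdfs:subClassOf>
            <owl:equivalentClass>
              <owl:Class>
                <owl:intersectionOf rdf:parseType="Collection">
                  <owl:Class rdf:about="http://x.org#B"/>
                  <owl:Restriction>
                    <owl:onProperty rdf:resource="http://x.org#q"/>
                    <owl:someValuesFrom rdf:resource="http://www.w3.org/2001/XMLSchema#string"/>
                  </owl:Restriction>
                </owl:intersectionOf>
              </owl:Class>
            </owl:equivalentClass>
          </owl:Class>
        </rdf:RDF>"""
        g = parse_owl(doc)
        A = "http://x.org#A"
        assert g.restrictions == {A: 2}
        assert g.object_property_assertions == {A: 1}
        assert g.datatype_property_assertions == {A: 2}  # restriction + domain
        # equivalence never creates subclass edges
        assert g.subclass_edges == ()

    def test_individuals_and_annotations(self):
        doc = b"""<?xml version="1.0"?>
        <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
                 xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
                 xmlns:owl="http://www.w3.org/2002/07/owl#">
          <owl:Class rdf:about="http://x.org#A">
            <rdfs:label>a label</rdfs:label>
            <rdfs:comment>a comment</rdfs:comment>
          </owl:Class>
          <owl:NamedIndividual rdf:about="http://x.org#a1">
            <rdf:type rdf:resource="http://x.org#A"/>
          </owl:NamedIndividual>
          <owl:NamedIndividual rdf:about="http://x.org#a2">
            <rdf:type rdf:resource="http://x.org#A"/>
          </owl:NamedIndividual>
        </rdf:RDF>"""
        g = parse_owl(doc)
        assert g.individuals == {"http://x.org#A": 2}
        assert g.annotation_assertions == {"http://x.org#A": 2}


class TestOntologyGraphInvariants:
    def test_rejects_self_edge(self):
        with pytest.raises(ValueError, match="self subclass"):
            OntologyGraph(classes=frozenset("A"), subclass_edges=(("A", "A"),))

    def test_rejects_edge_outside_classes(self):
        with pytest.raises(ValueError, match="outside"):
            OntologyGraph(classes=frozenset("A"), subclass_edges=(("A", "Z"),))

    def test_rejects_negative_tally(self):
        with pytest.raises(ValueError, match="nonnegative"):
            OntologyGraph(classes=frozenset("A"), annotation_assertions={"A": -1})

    def test_tallies_sum_to_totals(self):
        g = OntologyGraph(classes=frozenset("AB"), annotation_assertions={"A": 2, "B": 1})
        assert g.n_annotation_assertions == sum(g.annotation_assertions.values()) == 3


class TestRootToLeafPaths:
    def test_chain(self, chain_graph):
        paths = root_to_leaf_paths(chain_graph)
        assert paths == [(THING, "A", "B", "C")]
        assert path_length(paths[0]) == 3

    def test_diamond(self, diamond_graph):
        paths = root_to_leaf_paths(diamond_graph)
        assert len(paths) == 2
        assert all(path_length(p) == 3 and p[-1] == "D" for p in paths)

    def test_single_orphan(self):
        g = OntologyGraph(classes=frozenset("A"))
        assert root_to_leaf_paths(g) == [(THING, "A")]

    def test_cycle_rejected_with_cycle_named(self):
        g = OntologyGraph(classes=frozenset("AB"), subclass_edges=(("A", "B"), ("B", "A")))
        with pytest.raises(CyclicHierarchyError) as exc:
            root_to_leaf_paths(g)
        assert len(exc.value.cycle) == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_brute_force_on_random_dags(self, seed):
        rng = np.random.default_rng(1000 + seed)
        g = random_dag_graph(rng)
        got = sorted(p[1:] for p in root_to_leaf_paths(g))  # drop Thing sentinel
        assert got == sorted(brute_force_paths(g))
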