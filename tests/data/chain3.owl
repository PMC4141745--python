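<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
         xmlns:owl="http://www.w3.org/2002/07/owl#">
  <owl:Ontology rdf:about="http://example.org/chain3"/>
  <owl:Class rdf:about="http://example.org/chain3#A"/>
  <owl:Class rdf:about="http://example.org/chain3#B">
    <rdfs:subClassOf rdf:resource="http://example.org/chain3#A"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/chain3#C">
    <rdfs:subClassOf rdf:resource="http://example.org/chain3#B"/>
  </owl:Class>
</rdf:RDF>
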