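# Default quality model: 12 metrics -> 29 subcharacteristics -> 7 characteristics.
#
# The aggregation mechanism (1-5 band scoring, weighted averages, many-to-many
# metric/subcharacteristic mapping) is fixed by the framework; the constants in
# this file — threshold bands, the mapping matrix, the weights — are a
# documented reconstruction and every entry may be overridden by loading a
# custom YAML file.  Anchors honoured by the reconstruction: ANOnto feeds
# Knowledge Reuse, Redundancy and Controlled Vocabulary (annotation richness
# is what makes an ontology informative and term-homogeneous); NOCOnto and
# NACOnto feed Tangledness (multiple-parenthood distribution); LCOMOnto feeds
# Cohesion and Modularity.  Directions follow software-metric practice:
# complexity/coupling-style metrics are lower-better, richness-style metrics
# higher-better.
#
# Bands are the 4 ordered cut points splitting a metric's range into the five
# score bands.  higher_better: value < b1 -> 1, ..., value >= b4 -> 5;
# lower_better is the mirror image.

metrics:
  LCOMOnto: {direction: lower_better, bands: [2, 4, 6, 8]}
  WMCOnto: {direction: lower_better, bands: [5, 8, 11, 15]}
  DITOnto: {direction: lower_better, bands: [3, 5, 8, 12]}
  NACOnto: {direction: higher_better, bands: [1, 2, 3, 4]}
  NOCOnto: {direction: lower_better, bands: [2, 4, 6, 8]}
  RFCOnto: {direction: lower_better, bands: [3, 6, 9, 12]}
  NOMOnto: {direction: lower_better, bands: [2, 4, 6, 8]}
  PROnto: {direction: higher_better, bands: [0.2, 0.4, 0.6, 0.8]}
  AROnto: {direction: higher_better, bands: [0.2, 0.4, 0.6, 0.8]}
  INROnto: {direction: higher_better, bands: [0.2, 0.4, 0.6, 0.8]}
  CROnto: {direction: higher_better, bands: [0.2, 0.4, 0.6, 0.8]}
  ANOnto: {direction: higher_better, bands: [0.2, 0.4, 0.6, 0.8]}

subcharacteristics:
  Reference Ontology: {ANOnto: 1, PROnto: 1}
  Text Analysis: {ANOnto: 1, CROnto: 1}
  Infering: {AROnto: 1, INROnto: 1}
  Formalisation: {AROnto: 1, PROnto: 1}
  Formal Relation Support: {PROnto: 1, AROnto: 1}
  Consistency: {AROnto: 1, INROnto: 1, PROnto: 1}
  Schema And Value Reconciliation: {AROnto: 1, ANOnto: 1}
  Indexing And Linking: {PROnto: 1, INROnto: 1}
  Clustering And Similarity: {AROnto: 1, CROnto: 1}
  Guidance And Decision Trees: {NACOnto: 1, INROnto: 1}
  Results Representation: {CROnto: 1, INROnto: 1}
  Knowledge Reuse: {ANOnto: 1, NOMOnto: 1}
  Tangledness: {NOCOnto: 1, NACOnto: 1}
  Modularity: {LCOMOnto: 1, WMCOnto: 1}
  Knowledge Acquisition: {CROnto: 1, INROnto: 1, PROnto: 1}
  Modification Stability: {NOCOnto: 1, RFCOnto: 1, LCOMOnto: 1}
  Learnability: {WMCOnto: 1, DITOnto: 1, NOMOnto: 1, RFCOnto: 1, LCOMOnto: 1}
  Reusability: {WMCOnto: 1, DITOnto: 1, NOCOnto: 1, RFCOnto: 1}
  Changeability: {WMCOnto: 1, DITOnto: 1, NOCOnto: 1, RFCOnto: 1, LCOMOnto: 1}
  Availability: {RFCOnto: 1, NOMOnto: 1, WMCOnto: 1}
  Cohesion: {LCOMOnto: 1}
  Analysability: {WMCOnto: 1, DITOnto: 1, NOCOnto: 1, RFCOnto: 1, LCOMOnto: 1}
  Testability: {WMCOnto: 1, DITOnto: 1, NOCOnto: 1, RFCOnto: 1, LCOMOnto: 1}
  Adaptability: {DITOnto: 1, NOCOnto: 1, NOMOnto: 1, RFCOnto: 1}
  Consistent Search And Query: {ANOnto: 1, NOMOnto: 1, RFCOnto: 1}
  Replaceability: {WMCOnto: 1, DITOnto: 1, NOMOnto: 1}
  Recoverability: {WMCOnto: 1, RFCOnto: 1, LCOMOnto: 1}
  Controlled Vocabulary: {ANOnto: 1}
  Redundancy: {ANOnto: 1}

characteristics:
  Structural:
    Formalisation: 1
    Formal Relation Support: 1
    Cohesion: 1
    Tangledness: 1
    Redundancy: 1
    Consistency: 1
  Functional Adequacy:
    Reference Ontology: 1
    Text Analysis: 1
    Infering: 1
    Schema And Value Reconciliation: 1
    Indexing And Linking: 1
    Clustering And Similarity: 1
    Guidance And Decision Trees: 1
    Results Representation: 1
    Knowledge Reuse: 1
    Knowledge Acquisition: 1
    Controlled Vocabulary: 1
    Consistent Search And Query: 1
  Compatibility:
    Replaceability: 1
    Adaptability: 1
  Operability:
    Learnability: 1
  Reliability:
    Availability: 1
    Recoverability: 1
  Maintainability:
    Modularity: 1
    Reusability: 1
    Analysability: 1
    Changeability: 1
    Modification Stability: 1
    Testability: 1
  Transferability:
    Adaptability: 1
    Replaceability: 1
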