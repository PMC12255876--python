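# Mini semantic model: 12 categories, 15 predicates.
# Hand-sized stand-in for a full Biolink release carrying only the facts the
# engine reasons over: hierarchy parents, symmetry, inverses, canonical flags.
categories:
  NamedThing: {}
  ChemicalEntity: {parents: [NamedThing]}
  Drug: {parents: [ChemicalEntity]}
  SmallMoleculeDrug: {parents: [Drug]}
  Metabolite: {parents: [ChemicalEntity]}
  BiologicalEntity: {parents: [NamedThing]}
  Gene: {parents: [BiologicalEntity]}
  Protein: {parents: [BiologicalEntity]}
  Pathway: {parents: [BiologicalEntity]}
  DiseaseOrPhenotypicFeature: {parents: [NamedThing]}
  Disease: {parents: [DiseaseOrPhenotypicFeature]}
  PhenotypicFeature: {parents: [DiseaseOrPhenotypicFeature]}
predicates:
  related_to: {}
  subclass_of: {parents: [related_to]}
  interacts_with: {parents: [related_to], symmetric: true}
  physically_interacts_with: {parents: [interacts_with], symmetric: true}
  associated_with: {parents: [related_to], symmetric: true}
  close_match: {parents: [related_to], symmetric: true}
  affects: {parents: [related_to], canonical: true, inverse: affected_by}
  affected_by: {parents: [related_to], inverse: affects}
  treats: {parents: [affects], canonical: true, inverse: treated_by}
  treated_by: {parents: [affected_by], inverse: treats}
  regulates: {parents: [affects], canonical: true, inverse: regulated_by}
  regulated_by: {parents: [affected_by], inverse: regulates}
  participates_in: {parents: [related_to], canonical: true, inverse: has_participant}
  has_participant: {parents: [related_to], inverse: participates_in}
  produces: {parents: [related_to]}
category_prefixes:
  NamedThing: [TEST]
  ChemicalEntity: [CHEBI, DRUGBANK]
  Drug: [DRUGBANK, CHEBI]
  Gene: [NCBIGene]
  Protein: [UniProtKB]
  Disease: [MONDO, DOID]
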