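# Demo harmonization project (synthetic data; DEMO ontology ids are made up).
metadata: metadata.csv
dictionary: dictionary.csv
ontology: ontology.obo
maps_dir: maps
id_fields: [study_name, participant_id, sample_id]
edges:
  treatment: [treatment]
  disease: [disease]
  sex: [sex]
consensus: [sex]
enums:
  treatment:
    nodes: [DEMO:0000001]
    include_self: false
    allow_combinations: true
  disease:
    nodes: [DEMO:0000010]
constraints:
  - id: prostate-female
    if_attribute: disease
    if_values: [prostate carcinoma]
    then_attribute: sex
    forbidden_values: [Female]
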