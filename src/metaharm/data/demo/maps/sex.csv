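original_value,curated_ontology_term,curated_ontology_term_id,curated_ontology_term_db
male,Male,,
m,Male,,
female,Female,,
f,Female,,
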