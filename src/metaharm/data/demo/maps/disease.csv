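original_value,curated_ontology_term,curated_ontology_term_id,curated_ontology_term_db
t2d,type 2 diabetes mellitus,DEMO:0000012,DEMO
crc,colorectal carcinoma,DEMO:0000014,DEMO
prostate ca,prostate carcinoma,DEMO:0000015,DEMO
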