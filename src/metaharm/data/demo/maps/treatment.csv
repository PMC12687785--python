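original_value,curated_ontology_term,curated_ontology_term_id,curated_ontology_term_db
metformin,Metformin,DEMO:0000003,DEMO
sitagliptin,Sitagliptin,DEMO:0000004,DEMO
lantus,Insulin Glargine,DEMO:0000005,DEMO
solostar,Insulin Glargine,DEMO:0000005,DEMO
novorapid,Insulin Aspart,DEMO:0000006,DEMO
asa,Aspirin,DEMO:0000008,DEMO
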