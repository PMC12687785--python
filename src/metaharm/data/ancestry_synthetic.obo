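format-version: 1.2
ontology: ancestry-category-synthetic-snapshot
remark: SYNTHETIC snapshot for tests and examples. The 'ancestry category' node keeps its published CURIE; the eight child categories and their subtypes carry synthetic local ids and plausible labels. Not a redistribution of the HANCESTRO ontology.

[Term]
id: HANCESTRO:0001
name: ancestry

[Term]
id: HANCESTRO:0004
name: ancestry category
is_a: HANCESTRO:0001

[Term]
id: HANCESTRO:1000001
name: African
is_a: HANCESTRO:0004

[Term]
id: HANCESTRO:1000002
name: American
is_a: HANCESTRO:0004

[Term]
id: HANCESTRO:1000003
name: Asian
is_a: HANCESTRO:0004

[Term]
id: HANCESTRO:1000004
name: European
is_a: HANCESTRO:0004

[Term]
id: HANCESTRO:1000005
name: Greater Middle Eastern
synonym: "Middle Eastern" EXACT []
is_a: HANCESTRO:0004

[Term]
id: HANCESTRO:1000006
name: Hispanic or Latin American
synonym: "Hispanic" EXACT []
is_a: HANCESTRO:0004

[Term]
id: HANCESTRO:1000007
name: Native American
is_a: HANCESTRO:0004

[Term]
id: HANCESTRO:1000008
name: Oceanian
is_a: HANCESTRO:0004

[Term]
id: HANCESTRO:1000009
name: East Asian
is_a: HANCESTRO:1000003

[Term]
id: HANCESTRO:1000010
name: South Asian
is_a: HANCESTRO:1000003
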