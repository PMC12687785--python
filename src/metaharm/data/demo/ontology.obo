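format-version: 1.2
ontology: metaharm-demo-synthetic
remark: SYNTHETIC demo ontology (DEMO prefix); term labels are real-world drug/disease names, ids are made up for the worked example.

[Term]
id: DEMO:0000001
name: medication

[Term]
id: DEMO:0000002
name: antidiabetic agent
is_a: DEMO:0000001

[Term]
id: DEMO:0000003
name: Metformin
is_a: DEMO:0000002

[Term]
id: DEMO:0000004
name: Sitagliptin
is_a: DEMO:0000002

[Term]
id: DEMO:0000005
name: Insulin Glargine
synonym: "Lantus" EXACT []
is_a: DEMO:0000002

[Term]
id: DEMO:0000006
name: Insulin Aspart
synonym: "NovoRapid" EXACT []
is_a: DEMO:0000002

[Term]
id: DEMO:0000007
name: analgesic agent
is_a: DEMO:0000001

[Term]
id: DEMO:0000008
name: Aspirin
synonym: "acetylsalicylic acid" EXACT []
is_a: DEMO:0000007

[Term]
id: DEMO:0000010
name: disease

[Term]
id: DEMO:0000011
name: diabetes mellitus
is_a: DEMO:0000010

[Term]
id: DEMO:0000012
name: type 2 diabetes mellitus
is_a: DEMO:0000011

[Term]
id: DEMO:0000013
name: neoplasm
is_a: DEMO:0000010

[Term]
id: DEMO:0000014
name: colorectal carcinoma
is_a: DEMO:0000013

[Term]
id: DEMO:0000015
name: prostate carcinoma
is_a: DEMO:0000013
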