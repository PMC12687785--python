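name,kind,value_class,delimiter,dynamic_enum_nodes,details_partner,unit_attribute,required,members
treatment,multi,ontology-categorical,;,DEMO:0000001,,,false,
disease,multi,ontology-categorical,;,DEMO:0000010,,,false,
sex,single,free-text,;,,,,true,
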