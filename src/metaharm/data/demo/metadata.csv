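study_name,participant_id,sample_id,treatment,disease,sex
ZellerG_2014,p1,s1,metformin;sitagliptin;lantus;solostar;novorapid,t2d,male
ZellerG_2014,p1,s2,metformin,t2d,m
ZellerG_2014,p2,s1,asa,crc,female
LiJ_2017,p3,s1,,crc,male
LiJ_2017,p4,s1,,prostate ca,female
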