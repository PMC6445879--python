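rsid	rs1789953	rs6586282	rs6859667	rs921943
rs1789953	1	0.04	0	0
rs6586282	0.04	1	0	0
rs6859667	0	0	1	0.03
rs921943	0	0	0.03	1
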