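rsid	chrom	pos	ea	oa	eaf	beta	se	p	n
rs1789953	chr21	44482936	T	C	0.13	-0.04	0.02	0.12	121885
rs6586282	chr21	44478497	T	C	0.17	-0.04	0.02	0.04	121885
rs6859667	chr5	78745042	T	C	0.96	0.02	0.04	0.54	121885
rs921943	chr5	78316476	T	C	0.29	0.00	0.02	0.90	121885
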