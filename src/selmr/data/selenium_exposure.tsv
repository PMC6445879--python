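rsid	chrom	pos	ea	oa	eaf	z	p	n
rs1789953	chr21	44482936	T	C	0.14	5.52	3.4e-08	9639
rs6586282	chr21	44478497	T	C	0.17	-5.89	3.96e-09	9639
rs6859667	chr5	78745042	T	C	0.96	-6.92	4.4e-12	9639
rs921943	chr5	78316476	T	C	0.29	13.14	1.9e-39	9639
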