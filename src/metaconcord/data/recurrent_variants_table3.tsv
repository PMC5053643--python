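gene	cdna	protein	chrom	pos	ref	alt	primary_n	metastasis_n
PIK3CA	C1616G	P539R	chr2	70001616	C	G	1	1
PIK3CA	G1624A	E542K	chr2	70001624	G	A	1	1
PIK3CA	G1633A	E545K	chr2	70001633	G	A	3	2
PIK3CA	A3140G	H1047R	chr2	70003140	A	G	4	4
PIK3CA	A3140T	H1047L	chr2	70003140	A	T	2	2
PIK3CA	G353A	G118D	chr2	70000353	G	A	1	1
TP53	C152G	S51X	chr1	40000152	C	G	1	1
TP53	G128A	R43H	chr1	40000128	G	A	1	1
TP53	G317A	C106Y	chr1	40000317	G	A	1	1
TP53	T304C	Y102H	chr1	40000304	T	C	1	1
TP53	C421T	R141C	chr1	40000421	C	T	0	1
TP53	G422T	R141L	chr1	40000422	G	T	1	1
AKT1	G49A	E17K	chr3	80000049	G	A	2	2
ERBB2	T2264C	L755S	chr1	10002264	T	C	0	1
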