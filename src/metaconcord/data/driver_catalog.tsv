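gene	chrom	pos	ref	alt	catalog_count	weight
PIK3CA	chr2	70001616	C	G	32	2
PIK3CA	chr2	70001624	G	A	920	2
PIK3CA	chr2	70001633	G	A	1650	5
PIK3CA	chr2	70003140	A	G	3026	8
PIK3CA	chr2	70003140	A	T	310	4
PIK3CA	chr2	70000353	G	A	26	2
TP53	chr1	40000152	C	G	18	2
TP53	chr1	40000128	G	A	64	2
TP53	chr1	40000317	G	A	41	2
TP53	chr1	40000304	T	C	22	2
TP53	chr1	40000421	C	T	155	1
TP53	chr1	40000422	G	T	87	2
AKT1	chr3	80000049	G	A	412	4
ERBB2	chr1	10002264	T	C	121	1
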