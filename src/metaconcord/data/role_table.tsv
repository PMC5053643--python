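gene	role	hotspots
PIK3CA	oncogene	chr2:70001616:C:G,chr2:70001624:G:A,chr2:70001633:G:A,chr2:70003140:A:G,chr2:70003140:A:T,chr2:70000353:G:A
AKT1	oncogene	chr3:80000049:G:A
ERBB2	oncogene
TP53	tsg	any
PTEN	tsg	any
MYC	oncogene
FGFR1	oncogene
CCND1	oncogene
PAK1	oncogene
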