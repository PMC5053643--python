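gene	chrom	start	end
ERBB2	chr1	10000000	10200000
TP53	chr1	40000000	40050000
PTEN	chr2	10000000	10100000
MYC	chr2	30000000	30100000
PIK3CA	chr2	70000000	70100000
FGFR1	chr3	50000000	50100000
AKT1	chr3	80000000	80050000
PAK1	chr4	20000000	20100000
CCND1	chr4	60000000	60100000
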