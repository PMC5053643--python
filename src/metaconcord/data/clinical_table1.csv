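patient_id,age_at_diagnosis,pathological_type,grade,er_status,erbb2_status,prior_systemic_therapy,metastatic_site,delay_months,relapse_number
1,63,Mixed,2,positive,negative,"chemoT, hormonoT",Lymph nodes,26,1
2,52,Ductal,2,positive,negative,"chemoT, hormonoT",Skin,110,2
4,33,Ductal,3,positive,negative,"chemoT, hormonoT",Liver,35,1
5,56,Ductal,3,negative,negative,chemoT,Lymph nodes,25,1
6,41,Mixed,2,positive,positive,"chemoT, hormonoT",Skin,39,1
7,43,Medullary,3,negative,negative,chemoT,Muscle,27,1
8,61,Ductal,1,positive,,"chemoT, hormonoT",Liver,11,1
9,72,Lobular,2,positive,negative,"chemoT, hormonoT",Uterus,61,1
10,41,Ductal,1,positive,negative,"chemoT, hormonoT",Ovary,32,3
11,34,Ductal,,positive,negative,chemoT,Ovary,5,1
12,50,Ductal,,positive,,none,Lymph nodes,81,1
13,51,Ductal,3,negative,positive,hormonoT,Lung,36,1
14,34,Ductal,2,negative,,"chemoT, hormonoT",Bladder,23,1
15,35,Ductal,1,,,none,Lymph nodes,88,1
16,38,Ductal,3,positive,positive,chemoT,Skin,12,1
17,70,Lobular,1,negative,negative,chemoT,Skin,42,1
18,62,Ductal,3,negative,positive,"chemoT, trastuzumab, lapatinib, BKM120, T-DM1",Skin,25,3
20,60,Ductal,2,positive,positive,"chemoT, hormonoT, trastuzumab, lapatinib, T-DM1",Peritoneum,149,4
21,37,Ductal,,positive,negative,"chemoT, hormonoT",Lymph nodes,73,6
22,33,Ductal,3,positive,negative,"chemoT, hormonoT, trastuzumab",Liver,52,4
23,38,Metaplastic,3,negative,negative,chemoT,Liver,0,1
24,34,Ductal,,positive,negative,"chemoT, hormonoT",Liver,63,4
26,38,Ductal,3,positive,positive,"chemoT, hormonoT, trastuzumab",Ovary,78,1
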