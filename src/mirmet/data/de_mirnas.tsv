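mir_name	fold_change	p_value	status
hsa-miR-4773	-3.93085912	0.000279664	down-regulated
hsa-miR-365a-5p	-3.626016	1.63E-08	down-regulated
hsa-miR-196a-5p	-3.4089189	3.49E-09	down-regulated
hsa-miR-32-3p	-2.70841799	0.004499761	down-regulated
hsa-miR-187-3p	-2.53857823	0.001371206	down-regulated
hsa-miR-34a-5p	-2.49247468	7.61E-06	down-regulated
hsa-miR-21-3p	-2.27534465	6.12E-12	down-regulated
hsa-miR-377-5p	2.09915672	0.012601836	up-regulated
hsa-miR-296-3p	2.15683224	4.91E-05	up-regulated
hsa-miR-27b-3p	2.20970751	0	up-regulated
hsa-miR-106a-5p	2.23030507	1.26E-06	up-regulated
hsa-miR-125a-5p	2.30633203	1.22E-64	up-regulated
hsa-miR-203	2.46128988	0.011805279	up-regulated
hsa-miR-125b-5p	2.63566213	1.02E-13	up-regulated
hsa-miR-550a-3p	2.68366462	0.004077813	up-regulated
hsa-miR-4433-3p	2.69936903	0	up-regulated
hsa-miR-320d	2.77709983	5.31E-18	up-regulated
hsa-miR-320c	2.84603218	1.38E-149	up-regulated
hsa-miR-4286	3.01961409	4.51E-27	up-regulated
hsa-miR-378d	3.26900343	1.42E-08	up-regulated
hsa-miR-199b-5p	3.31684975	0	up-regulated
hsa-miR-491-5p	3.46128988	0.003037459	up-regulated
hsa-miR-550a-3-5p	3.63125615	2.58E-06	up-regulated
hsa-miR-550a-5p	3.63125615	2.58E-06	up-regulated
hsa-miR-18b-5p	3.9638412	0.000155776	up-regulated
hsa-miR-4454	4.12428748	4.66E-05	up-regulated
hsa-miR-125b-2-3p	7.08693234	0.000114317	up-regulated
hsa-miR-548av-5p	7.27965701	3.11E-05	up-regulated
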