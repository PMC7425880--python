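cytoband	variant_id	source	reported_EA	reported_EAF	reported_beta	reported_p	reported_phenotype	inverted_phenotype	best_phenotype	local_EA	local_EAF	local_beta	local_p
1p36.22	rs1194820	tarasov2009	G	0.77	-0.11	3.48e-7	cfPWV	False	bfPWV	G	0.73	0.019	1.69e-2
9q33.1	rs10125157	park2015	NA	NA	-0.06	8.25e-7	baPWV	False	cfPWV	C	0.05	0.004	6.83e-1
10p12.31	rs10764094	mitchell2012	C	0.47	-0.06	2.40e-7	cfPWV	True	bfPWV	C	0.49	-0.007	3.40e-1
13q34	rs3742207	tarasov2009	T	0.56	-0.09	5.16e-8	cfPWV	False	baPWV	G	0.33	0.003	1.11e-1
14q32.2	rs10782490	mitchell2012	C	0.47	-0.07	2.70e-9	cfPWV	True	baPWV	C	0.49	0.006	4.59e-3
14q32.2	rs1381273	mitchell2012	T	0.47	-0.06	1.90e-7	cfPWV	True	baPWV	T	0.46	0.004	2.73e-2
14q32.2	rs1381289	mitchell2012	T	0.44	-0.07	5.60e-11	cfPWV	True	baPWV	T	0.43	0.008	1.91e-4
14q32.2	rs1461587	mitchell2012	G	0.26	-0.07	1.50e-7	cfPWV	True	baPWV	G	0.22	0.008	1.15e-3
14q32.2	rs17773233	mitchell2012	T	0.23	-0.07	2.10e-8	cfPWV	True	baPWV	T	0.21	0.009	1.38e-4
14q32.2	rs2225442	mitchell2012	C	0.32	-0.07	1.20e-8	cfPWV	True	baPWV	C	0.40	0.007	7.98e-4
14q32.2	rs7152623	mitchell2012	A	0.38	-0.08	3.10e-15	cfPWV	True	baPWV	A	0.38	0.007	2.47e-4
14q32.2	rs8015529	mitchell2012	G	0.36	-0.07	2.50e-7	cfPWV	True	baPWV	G	0.34	0.004	3.56e-2
14q32.2	rs987514	mitchell2012	T	0.44	-0.07	4.50e-10	cfPWV	True	baPWV	T	0.41	0.006	1.54e-3
20p12.3	rs7271920	park2015	NA	NA	-0.17	7.20e-9	baPWV	False	cfPWV	T	0.12	-0.012	6.55e-2
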