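rsid	chrom	pos	effect_allele	other_allele	eaf	beta_sd	se_sd	locus
rs10936599	3	169492101	C	T	0.75	0.0931	0.0112	TERC
rs2293607	3	169482335	A	G	0.72	0.0792	0.0121	TERC
rs2736100	5	1286516	C	A	0.51	0.0838	0.0093	TERT
rs7675998	4	164007820	G	A	0.78	0.0745	0.0112	NAF1
rs9420907	10	105676465	C	A	0.87	0.0838	0.013	OBFC1
rs4387287	10	105677329	A	C	0.8	0.0745	0.0121	OBFC1
rs2487999	10	105675946	C	T	0.86	0.0699	0.014	OBFC1
rs8105767	19	22215441	G	A	0.29	0.0559	0.0093	ZNF208
rs755017	20	62421622	G	A	0.13	0.0652	0.013	RTEL1
rs11125529	2	54475866	A	C	0.14	0.0605	0.0121	ACYP2
rs6772228	3	58376019	T	A	0.93	0.0931	0.0186	PXK
rs3027234	17	8136092	C	T	0.77	0.0559	0.0112	CTC1
rs412658	19	22007281	T	C	0.35	0.0512	0.0093	ZNF676
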