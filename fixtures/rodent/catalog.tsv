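species	exon	kind	anchor_unit	position	length	alt
Castor_canadensis	1	deletion	codon	3	1	
Castor_canadensis	1	deletion	codon	20	1	
Castor_canadensis	1	insertion	codon	33	4	CAGG
Castor_canadensis	2	deletion	base	88	7	
Castor_canadensis	2	deletion	base	99	1	
Castor_canadensis	3	deletion	codon	12	1	
Heterocephalus_glaber	1	substitution	base	1	1	C
Heterocephalus_glaber	1	deletion	codon	21	1	
Ictidomys_tridecemlineatus	1	insertion	codon	1	1	C
Ictidomys_tridecemlineatus	2	insertion	codon	24	2	AG
Ictidomys_tridecemlineatus	4	deletion	base	76	7	
Ictidomys_tridecemlineatus	4	insertion	base	96	2	GG
Marmota_marmota	1	insertion	codon	1	1	C
Marmota_marmota	2	insertion	codon	24	2	AG
Marmota_marmota	4	deletion	base	76	7	
Marmota_marmota	4	insertion	base	96	2	GG
Marmota_marmota	1	insertion	codon	8	2	CA
Marmota_marmota	2	substitution	codon	26	1	A
Oryctolagus_cuniculus	1	deletion	codon	22	2	
Oryctolagus_cuniculus	2	deletion	codon	13	1	
Oryctolagus_cuniculus	2	deletion	codon	37	1	
Oryctolagus_cuniculus	3	insertion	codon	11	5	CAGCA
Oryctolagus_cuniculus	3	insertion	codon	16	1	G
Oryctolagus_cuniculus	3	deletion	codon	23	1	
Spermophilus_dauricus	1	insertion	codon	1	1	C
Spermophilus_dauricus	2	insertion	codon	24	2	AG
Spermophilus_dauricus	4	deletion	base	76	7	
Spermophilus_dauricus	4	insertion	base	96	5	GGCAG
Urocitellus_parryii	1	insertion	codon	1	1	C
Urocitellus_parryii	2	insertion	codon	24	2	AG
Urocitellus_parryii	4	deletion	base	76	7	
Urocitellus_parryii	4	insertion	base	96	2	GG
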