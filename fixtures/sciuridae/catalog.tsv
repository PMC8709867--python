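species	exon	kind	anchor_unit	position	length	alt
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
Spermophilus_dauricus	1	insertion	codon	1	1	C
Spermophilus_dauricus	2	insertion	codon	24	2	AG
Spermophilus_dauricus	4	deletion	base	76	7	
Spermophilus_dauricus	4	insertion	base	96	5	GGCAG
Urocitellus_parryii	1	insertion	codon	1	1	C
Urocitellus_parryii	2	insertion	codon	24	2	AG
Urocitellus_parryii	4	deletion	base	76	7	
Urocitellus_parryii	4	insertion	base	96	2	GG
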