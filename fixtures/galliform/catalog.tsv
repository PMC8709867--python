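species	exon	kind	anchor_unit	position	length	alt
Centrocercus_minimus	2	deletion	base	80	13	
Coturnix_japonica	2	substitution	base	48	1	T
Coturnix_japonica	2	substitution	base	50	1	A
Gallus_gallus	2	substitution	base	69	1	T
Lagopus_muta	2	deletion	base	80	13	
Lyrurus_tetrix	2	deletion	base	80	13	
Meleagris_gallopavo	2	substitution	base	7	2	GG
Meleagris_gallopavo	2	deletion	base	37	1	
Numida_meleagris	2	deletion	base	15	17	
Odontophorus_gujanensis	4	substitution	base	72	1	T
Pavo_cristatus	1	deletion	base	37	1	
Pavo_cristatus	4	deletion	base	31	1	
Pavo_muticus	1	deletion	base	37	1	
Pavo_muticus	4	deletion	base	31	1	
Syrmaticus_mikado	4	deletion	base	40	11	
Tympanuchus_cupido	2	deletion	base	80	13	
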