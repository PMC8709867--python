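species	exon	kind	anchor_unit	position	length	alt
Acinonyx_jubatus	2	insertion	base	11	1	G
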