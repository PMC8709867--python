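(Sciurus_vulgaris:35,(Marmota_marmota:14,(Ictidomys_tridecemlineatus:9,(Urocitellus_parryii:6,Spermophilus_dauricus:6):3):5):21);
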