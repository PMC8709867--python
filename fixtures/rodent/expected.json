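{
  "expected_events": 4,
  "expected_disrupted": [
    "Castor_canadensis",
    "Heterocephalus_glaber",
    "Ictidomys_tridecemlineatus",
    "Marmota_marmota",
    "Oryctolagus_cuniculus",
    "Spermophilus_dauricus",
    "Urocitellus_parryii"
  ],
  "intact_species": [
    "Sciurus_vulgaris"
  ],
  "putative_losses": []
}
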