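{
  "expected_events": 1,
  "expected_disrupted": [
    "Ictidomys_tridecemlineatus",
    "Marmota_marmota",
    "Spermophilus_dauricus",
    "Urocitellus_parryii"
  ],
  "intact_species": [
    "Sciurus_vulgaris"
  ],
  "putative_losses": []
}
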