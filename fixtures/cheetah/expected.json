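{
  "expected_events": 1,
  "expected_disrupted": [
    "Acinonyx_jubatus"
  ],
  "intact_species": [
    "Puma_concolor",
    "Felis_catus",
    "Panthera_tigris",
    "Crocuta_crocuta"
  ],
  "putative_losses": []
}
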