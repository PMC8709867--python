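{
  "expected_events": 8,
  "expected_disrupted": [
    "Centrocercus_minimus",
    "Coturnix_japonica",
    "Gallus_gallus",
    "Lagopus_muta",
    "Lyrurus_tetrix",
    "Meleagris_gallopavo",
    "Numida_meleagris",
    "Odontophorus_gujanensis",
    "Pavo_cristatus",
    "Pavo_muticus",
    "Syrmaticus_mikado",
    "Tympanuchus_cupido"
  ],
  "intact_species": [
    "Alectura_lathami",
    "Colinus_virginianus",
    "Callipepla_squamata",
    "Phasianus_colchicus",
    "Chrysolophus_pictus",
    "Penelope_pileata",
    "Anser_cygnoides",
    "Anas_platyrhynchos",
    "Anseranas_semipalmata"
  ],
  "putative_losses": [
    "Phasianus_colchicus",
    "Chrysolophus_pictus"
  ]
}
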