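((Anseranas_semipalmata:70,(Anser_cygnoides:25,Anas_platyrhynchos:25):45):10,(Alectura_lathami:66,(Penelope_pileata:62,(Numida_meleagris:55,((Odontophorus_gujanensis:30,(Colinus_virginianus:18,Callipepla_squamata:18):12):16,(Coturnix_japonica:44,((Pavo_cristatus:3,Pavo_muticus:3):32,(Gallus_gallus:34,((Meleagris_gallopavo:28,((Tympanuchus_cupido:10,Centrocercus_minimus:10):5,(Lagopus_muta:12,Lyrurus_tetrix:12):3):13):3,(Phasianus_colchicus:25,(Chrysolophus_pictus:18,Syrmaticus_mikado:18):7):6):3):1):9):2):9):7):4):14);
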