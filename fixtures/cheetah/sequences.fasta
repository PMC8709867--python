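>reference|focal|exon1|phase0
ATGCAGGCAAGCGCAGGAGGAGACCAGCAGAGCCGAGACACGAGCGCACCACCACAGGCA
ACGCGAGGAACGCGACGAGACGACGCACCACCAACCGGAA
>reference|focal|exon2|phase2
AGCGACGACCCAGTAAGCACCCAGCACAACACCAGCGCAAGCCAGACCGACGACAGCACG
GCACCAACGCAGAGCCCAACGCGAAGCCAGGACGACACGACCACC
>reference|focal|exon3|phase2
GACGACAGCAGCACGCCAAGCCCAGACGCACGAGGAGGAGACCAGCCAAGCGGAACCCGA
ACCCCAAGCGGACGACAGGACGGAGACCGA
>reference|focal|exon4|phase2
ACGCGAGCAGCACCAGGAAGCGACGGAGCAAGCACGGACCGACGAGCAGACACCGCAGGA
GCACAGCCAGCACCAAGCGACACCACCACGGCAAGCGGAGATAA
>Acinonyx_jubatus|focal|exon1|phase0
ATGCAGGCAAGCGCAGGAGGAGACCAGCAGAGCCGAGACACGAGCGCACCACCACAGGCA
ACGCGAGGAACGCGACGAGACGACGCACCACCAACCGGAA
>Acinonyx_jubatus|focal|exon2|phase2
AGCGACGACCCAGTAAGCACCCAGCATAACACCAGCGCAAGCCAGACCGACGACAGCACG
GCACCAACGCAGAGCCCAACGCGAAGCCAGGACGACACGACCACC
>Acinonyx_jubatus|focal|exon3|phase2
GACGACAGCAGCACGCCAAGCCCAGACGCACGAGGAGGAGACCAGCCAAGCGGAACCCGA
ACCCCAAGCGGACGACAGGACGGAGACCGA
>Acinonyx_jubatus|focal|exon4|phase2
ACGCGAGCAGCACCAGGAAGCGACGGAGCAAGCACGGACCGACGAGCAGACACCGCAGGA
GCACAGCCAGCACCAAGCGACACCACCACGGCAAGCGGAGATAA
>Puma_concolor|focal|exon1|phase0
ATGCAGGCAAGCGCAGGAGGAGACCAGCAGAGCCGAGACACGAGCGCACCACCACAGGCA
ACGCGAGGAACGCGACGAGACGACGCACCACCAACCGGAA
>Puma_concolor|focal|exon2|phase2
AGCGACGACCCAGTAAGCACCCAGCACAACACCAGCGCAAGCCAGACCGACGACAGCACG
GCACCAACGCAGAGCCCAACGCGAAGCCAGGACGACACGACCACC
>Puma_concolor|focal|exon3|phase2
GACGACAGCAGCACGCCAAGCCCAGACGCACGAGGAGGAGACCAGCCAAGCGGAACCCGA
ACCCCAAGCGGACGACAGGACGGAGACCGA
>Puma_concolor|focal|exon4|phase2
ACGCGAGCAGCACCAGGAAGCGACGGAGCAAGCACGGACCGACGAGCAGACACCGCAGGA
GCACAGCCAGCACCAAGCGACACCACCACGGCAAGCGGAGATAA
>Felis_catus|focal|exon1|phase0
ATGCAGGCAAGCGCAGGAGGAGACCAGCAGAGCCGAGACACGAGCGCACCACCACAGGCA
ACGCGAGGAACGCGACGAGACGACGCACCACCAACCGGAA
>Felis_catus|focal|exon2|phase2
AGCGACGACCCAGTAAGCACCCAGCACAACACCAGCGCAAGCCAGACCGACGACAGCACG
GCACCAACGCAGAGCCCAACGCGAAGCCAGGACGACACGACCACC
>Felis_catus|focal|exon3|phase2
GACGACAGCAGCACGCCAAGCCCAGACGCACGAGGAGGAGACCAGCCAAGCGGAACCCGA
ACCCCAAGCGGACGACAGGACGGAGACCGA
>Felis_catus|focal|exon4|phase2
ACGCGAGCAGCACCAGGAAGCGACGGAGCAAGCACGGACCGACGAGCAGACACCGCAGGA
GCACAGCCAGCACCAAGCGACACCACCACGGCAAGCGGAGATAA
>Panthera_tigris|focal|exon1|phase0
ATGCAGGCAAGCGCAGGAGGAGACCAGCAGAGCCGAGACACGAGCGCACCACCACAGGCA
ACGCGAGGAACGCGACGAGACGACGCACCACCAACCGGAA
>Panthera_tigris|focal|exon2|phase2
AGCGACGACCCAGTAAGCACCCAGCACAACACCAGCGCAAGCCAGACCGACGACAGCACG
GCACCAACGCAGAGCCCAACGCGAAGCCAGGACGACACGACCACC
>Panthera_tigris|focal|exon3|phase2
GACGACAGCAGCACGCCAAGCCCAGACGCACGAGGAGGAGACCAGCCAAGCGGAACCCGA
ACCCCAAGCGGACGACAGGACGGAGACCGA
>Panthera_tigris|focal|exon4|phase2
ACGCGAGCAGCACCAGGAAGCGACGGAGCAAGCACGGACCGACGAGCAGACACCGCAGGA
GCACAGCCAGCACCAAGCGACACCACCACGGCAAGCGGAGATAA
>Crocuta_crocuta|focal|exon1|phase0
ATGCAGGCAAGCGCAGGAGGAGACCAGCAGAGCCGAGACACGAGCGCACCACCACAGGCA
ACGCGAGGAACGCGACGAGACGACGCACCACCAACCGGAA
>Crocuta_crocuta|focal|exon2|phase2
AGCGACGACCCAGTAAGCACCCAGCACAACACCAGCGCAAGCCAGACCGACGACAGCACG
GCACCAACGCAGAGCCCAACGCGAAGCCAGGACGACACGACCACC
>Crocuta_crocuta|focal|exon3|phase2
GACGACAGCAGCACGCCAAGCCCAGACGCACGAGGAGGAGACCAGCCAAGCGGAACCCGA
ACCCCAAGCGGACGACAGGACGGAGACCGA
>Crocuta_crocuta|focal|exon4|phase2
ACGCGAGCAGCACCAGGAAGCGACGGAGCAAGCACGGACCGACGAGCAGACACCGCAGGA
GCACAGCCAGCACCAAGCGACACCACCACGGCAAGCGGAGATAA
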