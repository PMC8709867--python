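>reference|focal|exon1|phase0
ATGGACCCAACCGACCCAGGAAGCCAGAGCAGCGGAACCCAGACGGGAGCAGGAGCAACG
GGAAGCCGAAGCCCAAGCACCACGACGACGGACACGACGACCGGAGGACCAGACCGAACC
>reference|focal|exon2|phase0
GCAGGTAAAGTAAACGCACAGACGCAGGCAACGACCACGGGAACCGGAGACCGAACGAGC
ACGCGAAGCACCCAGCTAACAACCCCAGGAGCACCACGAACGCAGGACGGAGACGCAACG
>reference|focal|exon3|phase0
ACCGGAGCAACGACCGGACCAGACCAGCCAACGCAGAGCACGCCAACGGACGGACCACGA
GACGACCAGCAGGACCGAGAC
>reference|focal|exon4|phase0
AGCGCTAAAGTAAGACGAGACACCCGAGACCGAGACACGGACACGCCAACCGCAGACCGA
CGAAGCCAGCGAGGACAGCGAACCACCGCACAGCCACAGAGCTAA
>Castor_canadensis|focal|exon1|phase0
ATGGACCAACCGACCCAGGAAGCCAGAGCAGCGGAACCCAGACGGGAGCAGGAGCACGGG
AAGCCGAAGCCCAAGCACCACGACGACGGACACGACGCAGGACCGGAGGACCAGACCGAA
CC
>Castor_canadensis|focal|exon2|phase1
GCAGGTAAAGTAAACGCACAGACGCAGGCAACGACCACGGGAACCGGAGACCGAACGAGC
ACGCGAAGCACCCAGCTAACAACCCCACACGACGCAGGACGGAGACGCAACG
>Castor_canadensis|focal|exon3|phase0
ACCGGAGCAACGACCGGACCAGACCAGCCAACGAGAGCACGCCAACGGACGGACCACGAG
ACGACCAGCAGGACCGAGAC
>Castor_canadensis|focal|exon4|phase1
AGCGCTAAAGTAAGACGAGACACCCGAGACCGAGACACGGACACGCCAACCGCAGACCGA
CGAAGCCAGCGAGGACAGCGAACCACCGCACAGCCACAGAGCTAA
>Heterocephalus_glaber|focal|exon1|phase0
CTGGACCCAACCGACCCAGGAAGCCAGAGCAGCGGAACCCAGACGGGAGCAGGAGCAACG
GAAGCCGAAGCCCAAGCACCACGACGACGGACACGACGACCGGAGGACCAGACCGAACC
>Heterocephalus_glaber|focal|exon2|phase1
GCAGGTAAAGTAAACGCACAGACGCAGGCAACGACCACGGGAACCGGAGACCGAACGAGC
ACGCGAAGCACCCAGCTAACAACCCCAGGAGCACCACGAACGCAGGACGGAGACGCAACG
>Heterocephalus_glaber|focal|exon3|phase1
ACCGGAGCAACGACCGGACCAGACCAGCCAACGCAGAGCACGCCAACGGACGGACCACGA
GACGACCAGCAGGACCGAGAC
>Heterocephalus_glaber|focal|exon4|phase1
AGCGCTAAAGTAAGACGAGACACCCGAGACCGAGACACGGACACGCCAACCGCAGACCGA
CGAAGCCAGCGAGGACAGCGAACCACCGCACAGCCACAGAGCTAA
>Ictidomys_tridecemlineatus|focal|exon1|phase0
ATGCGACCCAACCGACCCAGGAAGCCAGAGCAGCGGAACCCAGACGGGAGCAGGAGCAAC
GGGAAGCCGAAGCCCAAGCACCACGACGACGGACACGACGACCGGAGGACCAGACCGAAC
C
>Ictidomys_tridecemlineatus|focal|exon2|phase2
GCAGGTAAAGTAAACGCACAGACGCAGGCAACGACCACGGGAACCGGAGACCGAACGAGC
ACGCGAAGCACCAGCAGCTAACAACCCCAGGAGCACCACGAACGCAGGACGGAGACGCAA
CG
>Ictidomys_tridecemlineatus|focal|exon3|phase0
ACCGGAGCAACGACCGGACCAGACCAGCCAACGCAGAGCACGCCAACGGACGGACCACGA
GACGACCAGCAGGACCGAGAC
>Ictidomys_tridecemlineatus|focal|exon4|phase0
AGCGCTAAAGTAAGACGAGACACCCGAGACCGAGACACGGACACGCCAACCGCAGACCGA
CGAAGCCAGCGAGGACCACCGCACAGCCAGGCAGAGCTAA
>Marmota_marmota|focal|exon1|phase0
ATGCGACCCAACCGACCCAGGAAGCCACAGAGCAGCGGAACCCAGACGGGAGCAGGAGCA
ACGGGAAGCCGAAGCCCAAGCACCACGACGACGGACACGACGACCGGAGGACCAGACCGA
ACC
>Marmota_marmota|focal|exon2|phase0
GCAGGTAAAGTAAACGCACAGACGCAGGCAACGACCACGGGAACCGGAGACCGAACGAGC
ACGCGAAGCACCAGCAGATAACAACCCCAGGAGCACCACGAACGCAGGACGGAGACGCAA
CG
>Marmota_marmota|focal|exon3|phase1
ACCGGAGCAACGACCGGACCAGACCAGCCAACGCAGAGCACGCCAACGGACGGACCACGA
GACGACCAGCAGGACCGAGAC
>Marmota_marmota|focal|exon4|phase1
AGCGCTAAAGTAAGACGAGACACCCGAGACCGAGACACGGACACGCCAACCGCAGACCGA
CGAAGCCAGCGAGGACCACCGCACAGCCAGGCAGAGCTAA
>Oryctolagus_cuniculus|focal|exon1|phase0
ATGGACCCAACCGACCCAGGAAGCCAGAGCAGCGGAACCCAGACGGGAGCAGGAGCAACG
GGACCGAAGCCCAAGCACCACGACGACGGACACGACGACCGGAGGACCAGACCGAACC
>Oryctolagus_cuniculus|focal|exon2|phase2
GCAGGTAAAGTAAACGCACAGACGCAGGCAACGACCCGGGAACCGGAGACCGAACGAGCA
CGCGAAGCACCCAGCTAACAACCCCAGGAGCACCACGAACGCAGGACGAGACGCAACG
>Oryctolagus_cuniculus|focal|exon3|phase1
ACCGGAGCAACGACCGGACCAGACCAGCCAACGCAGCACAGAGCACGCCAACGGGACGGA
CCACGAGACGACAGCAGGACCGAGAC
>Oryctolagus_cuniculus|focal|exon4|phase2
AGCGCTAAAGTAAGACGAGACACCCGAGACCGAGACACGGACACGCCAACCGCAGACCGA
CGAAGCCAGCGAGGACAGCGAACCACCGCACAGCCACAGAGCTAA
>Spermophilus_dauricus|focal|exon1|phase0
ATGCGACCCAACCGACCCAGGAAGCCAGAGCAGCGGAACCCAGACGGGAGCAGGAGCAAC
GGGAAGCCGAAGCCCAAGCACCACGACGACGGACACGACGACCGGAGGACCAGACCGAAC
C
>Spermophilus_dauricus|focal|exon2|phase2
GCAGGTAAAGTAAACGCACAGACGCAGGCAACGACCACGGGAACCGGAGACCGAACGAGC
ACGCGAAGCACCAGCAGCTAACAACCCCAGGAGCACCACGAACGCAGGACGGAGACGCAA
CG
>Spermophilus_dauricus|focal|exon3|phase0
ACCGGAGCAACGACCGGACCAGACCAGCCAACGCAGAGCACGCCAACGGACGGACCACGA
GACGACCAGCAGGACCGAGAC
>Spermophilus_dauricus|focal|exon4|phase0
AGCGCTAAAGTAAGACGAGACACCCGAGACCGAGACACGGACACGCCAACCGCAGACCGA
CGAAGCCAGCGAGGACCACCGCACAGCCAGGCAGCAGAGCTAA
>Urocitellus_parryii|focal|exon1|phase0
ATGCGACCCAACCGACCCAGGAAGCCAGAGCAGCGGAACCCAGACGGGAGCAGGAGCAAC
GGGAAGCCGAAGCCCAAGCACCACGACGACGGACACGACGACCGGAGGACCAGACCGAAC
C
>Urocitellus_parryii|focal|exon2|phase2
GCAGGTAAAGTAAACGCACAGACGCAGGCAACGACCACGGGAACCGGAGACCGAACGAGC
ACGCGAAGCACCAGCAGCTAACAACCCCAGGAGCACCACGAACGCAGGACGGAGACGCAA
CG
>Urocitellus_parryii|focal|exon3|phase0
ACCGGAGCAACGACCGGACCAGACCAGCCAACGCAGAGCACGCCAACGGACGGACCACGA
GACGACCAGCAGGACCGAGAC
>Urocitellus_parryii|focal|exon4|phase0
AGCGCTAAAGTAAGACGAGACACCCGAGACCGAGACACGGACACGCCAACCGCAGACCGA
CGAAGCCAGCGAGGACCACCGCACAGCCAGGCAGAGCTAA
>Sciurus_vulgaris|focal|exon1|phase0
ATGGACCCAACCGACCCAGGAAGCCAGAGCAGCGGAACCCAGACGGGAGCAGGAGCAACG
GGAAGCCGAAGCCCAAGCACCACGACGACGGACACGACGACCGGAGGACCAGACCGAACC
>Sciurus_vulgaris|focal|exon2|phase0
GCAGGTAAAGTAAACGCACAGACGCAGGCAACGACCACGGGAACCGGAGACCGAACGAGC
ACGCGAAGCACCCAGCTAACAACCCCAGGAGCACCACGAACGCAGGACGGAGACGCAACG
>Sciurus_vulgaris|focal|exon3|phase0
ACCGGAGCAACGACCGGACCAGACCAGCCAACGCAGAGCACGCCAACGGACGGACCACGA
GACGACCAGCAGGACCGAGAC
>Sciurus_vulgaris|focal|exon4|phase0
AGCGCTAAAGTAAGACGAGACACCCGAGACCGAGACACGGACACGCCAACCGCAGACCGA
CGAAGCCAGCGAGGACAGCGAACCACCGCACAGCCACAGAGCTAA
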