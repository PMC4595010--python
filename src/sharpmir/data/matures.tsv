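name	sequence
Hvi-miR29035	ugcaacaguucuggcuuggcaa
Hvi-miR13059	uuuguucugaauggcacgucgg
Hvi-miR28196	uaguuuacaucaucgacugugc
Hvi-miR9237	uguuugaacaccucggccuuua
Hvi-miR19117	uccaguaguaagccucaaacca
Hvi-miR24402	uuauaguuccuugcgcuacguu
Hvi-miR66	ugauaagucagacauuugaaag
Hvi-miR41359	uagaucuaguucccuucugcug
Hvi-miR29828	ucugcuugcuccguaccuacuu
Hvi-miR2062	gaagaaguacuuggugccguca
Hvi-miR20768	uaugugauucuuguacucggcu
Hvi-miR91	uuuuuguuggaaaccgacaacc
Hvi-miR24657	agaaagacuauugcagagcugc
Hvi-miR6225	ggauaucauagagggacuugaa
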