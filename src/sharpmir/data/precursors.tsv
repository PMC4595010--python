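name	sequence
Hvi-miR29035	uuuuacuccauauaacauuguucaaagauucauugggguuuugggauuuaccucugagacauuuuugcaacaguucuggcuuggcaagau
Hvi-miR13059	uuuguucugaauggcacgucggagacugggcaggguugcgcaguaggcuucugaguuaaucgucauuccucgcg
Hvi-miR28196	guuacggggaaucggaauaaaagacugaauuaguuuacaucaucgacugugcucg
Hvi-miR9237	uguuugaacaccucggccuuuaaguaaccccacagaaaaaagucacaugggguuaaaucgggugaucgcgcuggccaca
Hvi-miR19117	uccaguaguaagccucaaaccaaauguuguuguagauuacaacaaguauaugugugggguagacaagcaggacc
Hvi-miR24402	ucuggugcuugugguuggugauaauucuacagcauuuauuauugcuuguucauuauuauaguuccuugcgcuacguu
Hvi-miR66	ugauaagucagacauuugaaagaugcgucgccgguacgaggaccgugcgaucagcugaaaguuauucagagucaccaagaag
Hvi-miR41359	gcagcagaaggaaacuaauacaagaaacaaaaacuuagaucuaguucccuucugcug
Hvi-miR29828	uucuuguagguacauuggagcagcucuuuguaaaggcacucugcuugcuccguaccuacuucga
Hvi-miR2062	gaagaaguacuuggugccgucagacuugacugucggucaguuuuacuucuug
Hvi-miR20768	uaugugauucuuguacucggcuuguauugccucucuuucugacucaaauuaccuuuaaguuuagcuugguaggaaucgcauguauc
Hvi-miR91	uuuggcugucguguuuggaauuaacaaguucaggcguuaccuagaacauaaagaauuuuuguuggaaaccgacaaccagg
Hvi-miR24657	agaaagacuauugcagagcugcagagacagaggcucggcccucauucucagcugcgacugcaaugcucaccacacgu
Hvi-miR6225	guucaagccucuguaugauauaaauguauguauguugacaaaaggauaucauagagggacuugaacuu
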