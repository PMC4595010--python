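name	description	start	end
Hvi-miR29035	Uncharacterized protein with oxidoreductase activity	395	485
Hvi-miR13059	Transposable element	817	891
Hvi-miR28196	Uncharacterized protein	159	214
Hvi-miR9237	TC3 type transposable element	739	818
Hvi-miR19117	Transposable element	125	199
Hvi-miR24402	TC3 type transposable element	877	957
Hvi-miR66	Uncharacterized	188	274
Hvi-miR41359	Transposable element	195	255
Hvi-miR29828	Ion transport protein involved in response to abiotic stress	169	233
Hvi-miR2062	Gamma amino butyric acid receptor	147	199
Hvi-miR20768	Uncharacterized	75	161
Hvi-miR91	Retro transposable element	195	275
Hvi-miR24657	Transposable element	30	107
Hvi-miR6225	Uncharacterized transmembrane protein	737	805
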