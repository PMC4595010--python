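name	total	mature_reads	star_reads
Hvi-miR29035	326	324	2
Hvi-miR13059	234	112	122
Hvi-miR28196	69	48	21
Hvi-miR9237	23	22	1
Hvi-miR19117	19	18	1
Hvi-miR24402	22	21	1
Hvi-miR66	12	10	2
Hvi-miR41359	13	13	0
Hvi-miR29828	1860	1007	853
Hvi-miR2062	95	94	1
Hvi-miR20768	16	15	1
Hvi-miR91	145	143	2
Hvi-miR24657	12	10	2
Hvi-miR6225	24	24	0
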