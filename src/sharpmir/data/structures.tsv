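name	structure
Hvi-miR29035	…….(((..((..(((((((((((((((…(((((……….)))))…)).))))))).))))))..))…)))……
Hvi-miR13059	…((…(((((((((.((((((((((.((……)).))))….))))))))…..)))))))…)).
Hvi-miR28196	..(((((….((((……((((((…))))))……)))))))))….
Hvi-miR9237	…………..((((……((((((((..((……))…))))))))…..((((….))))))))…
Hvi-miR19117	(((.((.((..((((((…((.(((((((((((…)))))))).))).))..))))))..))..)).)))..
Hvi-miR24402	..((((((….((…((((((((…((((((……..))).)))..))))))))….))..))))))….
Hvi-miR66	……….(((.((((((.((((((((((((((……)))).)))))..))…..))).)))))))))………
Hvi-miR41359	.((((((((((.(((((((..(((………)))..)).))))).))))))))))
Hvi-miR29828	…..((((((((…((((((((….(((….)))….)).))))))))))))))…..
Hvi-miR2062	.((((((((……((((.(((……))).))))……)))))))).
Hvi-miR20768	(((((((((((((…..(((…….)))……………………((((…..)))).)))))))))))))….
Hvi-miR91	.((((.(((((.((((….((((((((((((((…..))).))))………..)))))))))))))))).)))).
Hvi-miR24657	…..((.((((((((.((.((.((((..((((……))))..)))).)).))..)))))))).))………
Hvi-miR6225	(((((((.((((.((((((((…….(((……)))…..)))))))).)))).)))))))..
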