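population,region,n,latitude,longitude,latitude_printed,longitude_printed,coordinates_flagged
Bantu N.E.,Africa,11,-3,37,3 S,37 E,0
Bantu S,Africa,8,-29,30,29 S,30 E,0
Biaka Pygmies,Africa,29,30.5,66.5,30-31,66-67 E,1
Mandenka,Africa,23,12,-12,12 N,12 W,0
Mbuti Pygmies,Africa,12,1,29,1 N,29 E,0
San,Africa,7,-21,20,21 S,20 E,0
Yoruba,Africa,23,8,5,6-10 N,2-8 E,0
Mozabite,Middle East,27,32,3,32 N,3 E,0
Bedouin,Middle East,46,4,17,4 N,17 E,1
Palestinian,Middle East,42,32,35,32 N,35 E,0
Druze,Middle East,46,32,35,32 N,35 E,0
Adygei,Europe,17,44,39,44 N,39 E,0
French,Europe,26,46,2,46 N,2 E,0
French Basque,Europe,22,43,0,43 N,0,0
North Italian,Europe,14,46,10,46 N,10 E,0
Orcadian,Europe,13,59,-3,59 N,3 W,0
Russian,Europe,24,61,40,61 N,39-41 E,0
Sardinian,Europe,24,40,9,40 N,9 E,0
Tuscan,Europe,8,43,11,43 N,11 E,0
Pathan,Central-South Asia,21,33.5,70.5,32-35 N,6972 E,1
Makrani,Central-South Asia,25,26,64,26 N,62-66 E,0
Kalash,Central-South Asia,24,36,71.5,35-37 N,71-72 E,0
Hazara,Central-South Asia,22,33.5,70,33-34 N,70 E,0
Balochi,Central-South Asia,23,30.5,66.5,30-31 N,66-67 E,0
Barusho,Central-South Asia,20,31,35,31 N,35 E,1
Brahui,Central-South Asia,22,36.5,74,36-37 N,73-75 E,0
Sindhi,Central-South Asia,23,25.5,69,24-27 N,68-70 E,0
Uygur,Central-South Asia,9,44,81,44 N,81 E,0
Cambodian,East Asia,11,12,105,12 N,105 E,0
Dai,East Asia,8,21,100,21 N,100 E,0
Daur,East Asia,9,48.5,124,48-49 N,124 E,0
Han,East Asia,46,37.5,114,36-39 N,108-120 E,0
Hezhen,East Asia,10,47.5,133.5,47-48 N,132-135 E,0
Japanese,East Asia,31,38,138,38 N,138 E,0
Lahu,East Asia,10,22,100,22 N,100 E,0
Miaozu,East Asia,8,28,109,28 N,109 E,0
Mongola,East Asia,10,45,111,45 N,111 E,0
Naxi,East Asia,10,26,100,26 N,100 E,0
Orogen,East Asia,9,50.5,126.5,48-53 N,122-131 E,0
She,East Asia,10,27,119,27 N,119 E,0
Tu,East Asia,9,36,101,36 N,101 E,0
Tujia,East Asia,7,29,109,29 N,109 E,0
Xibo,East Asia,8,43.5,81.5,43-44 N,81-82 E,0
Yakut,East Asia,22,63,129.5,62-64 N,129-130 E,0
Yizu,East Asia,10,28,103,28 N,103 E,0
Papuan,Oceania,16,-4,143,4 S,143 E,0
NAN Melanesian,Oceania,21,-6,155,6 S,155 E,0
Karitiana,America,24,-10,-63,10 S,63 W,0
Maya,America,24,19,-91,19 N,91 W,0
Pima,America,25,29,-108,29 N,108 W,0
Surui,America,15,-11,-62,11 S,62 W,0
Colombian,America,12,3,-68,3 N,68 W,0
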