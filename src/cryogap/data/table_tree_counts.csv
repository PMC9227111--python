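genus,gts_trees,wfo_synonym,wfo_accepted,wfo_unchecked,wfo_doubtful
Andira,29,31,40,1,NA
Astragalus,0,2308,3108,146,23
Castanospermum,1,2,1,NA,NA
Cojoba,14,20,15,2,NA
Copaifera,34,38,45,4,1
Cordyla,5,5,5,1,NA
Crotalaria,6,596,716,16,24
Cynometra,108,72,88,4,NA
Detarium,3,4,3,NA,1
Dipteryx,11,16,12,2,NA
Erythrina,107,152,132,16,10
Inga,266,504,279,28,13
Kanaloa,0,NA,1,NA,NA
Marmaroxylon,0,9,NA,NA,NA
Pentaclethra,3,7,3,1,NA
Prioria,11,NA,14,NA,NA
Saraca,10,23,11,1,NA
Senna,110,36,282,20,NA
Sesbania,13,57,63,11,NA
Sophora,29,121,63,16,NA
Strongylodon,0,12,16,3,NA
Swartzia,185,79,199,14,NA
Vicia,0,404,248,86,2
Vigna,0,202,104,15,NA
Zygia,55,38,66,4,NA
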