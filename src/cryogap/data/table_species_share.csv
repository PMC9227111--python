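species,n_articles,family,n_exceptional_in_family,family_articles
Carica papaya,20,Caricaceae,1,20
Cocos nucifera,21,Arecaceae,37,71
Coffea arabica,17,Rubiaceae,32,35
Citrus sinensis,14,Rutaceae,35,69
Elaeis guineensis,12,Arecaceae,37,71
Mangifera indica,11,Anacardiaceae,10,14
Theobroma cacao,11,Malvaceae,12,29
Trichilia dregeana,10,Meliaceae,25,30
Artocarpus heterophyllus,9,Moraceae,18,20
Castanea sativa,8,Fagaceae,24,37
Quercus robur,8,Fagaceae,24,37
Diospyros kaki,7,Ebenaceae,6,9
Persea americana,7,Lauraceae,24,9
Citrus limon,6,Rutaceae,35,69
Ekebergia capensis,6,Meliaceae,25,30
Hevea brasiliensis,6,Euphorbiaceae,2,30
Passiflora edulis,5,Passifloraceae,1,14
Wasabia japonica,5,Brassicaceae,2,49
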