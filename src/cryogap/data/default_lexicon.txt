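# Default keyword lexicon for screening plant-cryopreservation literature.
# Editable: one entry per line; trailing * is a letter-suffix wildcard;
# matching is case-insensitive whole-word over title + abstract.

[positive]
cryopreserv*
cryogenic
cryostorage
liquid nitrogen
vitrification
cryobank*

[negative]
mammal*
sperm
review

[review]
human

[nonseed:algae]
algae
alga
microalga*
cyanobacter*

[nonseed:fungi]
fungus
fungi
fungal
yeast
mycelium

[nonseed:bryophyte]
moss
mosses
bryophyte*
liverwort*
protonema*

[nonseed:pteridophyte]
fern*
pteridophyte*

[tissue:DormantBud]
dormant bud*
winter bud*

[tissue:Embryo]
zygotic embryo*
embryo ax*
embryonic ax*
excised embryo*

[tissue:InVitro]
in vitro
shoot tip*
somatic embryo*
meristem*
protocorm*
callus

[tissue:Pollen]
pollen

[tissue:Seed]
seed
seeds

[common_names]
apple = Malus
papaya = Carica
coconut = Cocos
coffee = Coffea
mango = Mangifera
oil palm = Elaeis
avocado = Persea
banana = Musa
potato = Solanum
grapevine = Vitis
oak = Quercus
cacao = Theobroma

[exclusions]
Aa
Cotyledon
Cuba
India
Ion
Medium
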