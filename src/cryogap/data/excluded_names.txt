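# Homograph genus names excluded from scientific-name matching: these genera
# are spelled like ordinary words or place names and, in cryopreservation
# titles/abstracts, essentially always refer to the ordinary word.
# Extend freely; one name per line.
Aa
Cotyledon
Cuba
India
Ion
Medium
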