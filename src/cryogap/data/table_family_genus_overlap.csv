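family,exc_genera,lit_genera,n_common
Arecaceae,23,14,7
Fabaceae,24,36,5
Orchidaceae,19,44,10
Rutaceae,6,5,1
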