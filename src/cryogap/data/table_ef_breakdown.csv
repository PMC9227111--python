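family,total,ef1,ef2,ef3,ef4
Dipterocarpaceae,59,0,55,4,0
Rhizophoraceae,15,0,15,0,0
Pittosporaceae,10,1,0,10,0
Myristicaceae,9,0,7,2,0
Podocarpaceae,7,0,5,2,0
Santalaceae,7,1,1,5,0
Nymphaeaceae,6,0,4,1,1
Cyperaceae,5,0,0,5,1
Nyctaginaceae,5,0,4,1,0
Urticaceae,5,0,0,5,1
Cymodoceaceae,4,0,4,0,0
Lecythidaceae,4,0,4,0,0
Dilleniaceae,3,0,0,0,3
Scrophulariaceae,3,0,0,3,0
Calophyllaceae,2,0,2,0,0
Chrysobalanaceae,2,0,2,0,0
Elaeocarpaceae,2,1,1,0,0
Hydrangeaceae,2,0,0,2,0
Zosteraceae,2,0,2,0,0
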