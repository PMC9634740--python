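ligand	receptor	energy
Luteolin	MAPK8	-9.9
Quercetin	MAPK8	-9.7
Kaempferol	MAPK8	-9.2
Luteolin	RELA	-9.2
Quercetin	RELA	-9.2
Isorhamnetin	AKT1	-9.1
Isorhamnetin	MAPK8	-9.1
Quercetin	AKT1	-8.9
Luteolin	AKT1	-8.7
Luteolin	CCND1	-8.7
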