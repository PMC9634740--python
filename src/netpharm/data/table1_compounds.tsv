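MOL ID	Molecule name	OB	DL
MOL002235	Eupatin	50.8	0.41
MOL000354	Isorhamnetin	49.6	0.31
MOL000359	Sitosterol	36.91	0.75
MOL004083	Tamarixetin	32.86	0.31
MOL004112	Patuletin	53.11	0.34
MOL000422	Kaempferol	41.88	0.24
MOL000449	Stigmasterol	43.83	0.76
MOL004609	Areapillin	48.96	0.41
MOL005229	Artemetin	49.55	0.48
MOL000006	Luteolin	36.16	0.25
MOL007274	Skrofulein	30.35	0.3
MOL007389	Artemisitene	54.36	0.31
MOL007400	Vicenin-2_qt	45.84	0.21
MOL007401	Cirsiliol	43.46	0.34
MOL007404	Vitexin_qt	52.18	0.21
MOL007412	DMQT	42.6	0.37
MOL007415	[(2S)-2-[[(2S)-2-(benzoylamino)-3-phenylpropanoyl]amino]-3-phenylpropyl] acetate	58.02	0.52
MOL007423	6,8-di-c-glucosylapigenin_qt	59.85	0.21
MOL007424	Artemisinin	49.88	0.31
MOL007425	Dihydroartemisinin	50.75	0.3
MOL007426	Deoxyartemisinin	54.47	0.26
MOL000098	Quercetin	46.43	0.28
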