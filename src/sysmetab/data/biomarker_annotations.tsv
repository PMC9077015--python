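query	hit	hmdb	kegg
Leucine	l-Leucine	HMDB00687	C00123
Valine	l-Valine	HMDB00883	C00183
Lactate	l-Lactic acid	HMDB00190	C00186
Alanine	l-Alanine	HMDB00161	C00041
Arginine	l-Arginine	HMDB00517	C00062
Acetate	Acetic acid	HMDB00042	C00033
Methionine	l-Methionine	HMDB00696	C00073
Glutamate	d-Glutamic acid	HMDB03339	C00217
Glutamine	l-Glutamine	HMDB00641	C00064
Creatine	Creatine	HMDB00064	C00300
Taurine	Taurine	HMDB00251	C00245
Threonine	l-Threonine	HMDB00167	C00188
Myo-inositol	Myo-inositol	HMDB00211	C00137
Glycerol	Glycerol	HMDB00131	C00116
Betaine	Betaine	HMDB00043	C00719
TMAO	Trimethylamine N-oxide	HMDB00925	C01104
Tyrosine	l-Tyrosine	HMDB00158	C00082
Beta-glucose	Beta-d-glucose	HMDB00516	C00221
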