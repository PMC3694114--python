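refsetname	setsize	setscore_rnaseq	setscore_microarray
cotinine	6	-0.598	-0.377
morantel	5	-0.557	-0.366
tobramycin	4	-0.671	-0.348
trioxysalen	4	-0.658	-0.383
pentoxyverine	4	-0.601	-0.369
levamisole	4	-0.569	-0.356
trimetazidine	4	-0.552	-0.370
chlorphenesin	4	-0.548	-0.398
oxprenolol	4	-0.535	-0.336
zomepirac	4	-0.533	-0.330
lysergol	4	-0.505	-0.349
fosfosal	4	-0.428	-0.280
sertaconazole	4	-0.411	-0.256
abamectin	4	-0.392	-0.245
saquinavir	4	-0.359	-0.243
ipratropium bromide	3	-0.564	-0.365
furazolidone	4	0.602	0.344
5186223	1	0.701	0.504
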