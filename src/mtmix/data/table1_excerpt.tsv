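region	sample_id	profile
Iberia	20	rCRS
Iberia	21	16093
Iberia	22	16093 16189 16293
Iberia	23	16093 16224 16311
Iberia	1263	16093 16293
Iberia	1264	16069 16126
Iberia	2135	16093 16189 16224 16311
Iberia	2136	16093 16224 16311
Iberia	2575	16126 16294 16296 16304
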