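# HVS-I excerpt recoded as a site-by-haplotype indicator table with one
# realized column of scaled variant peak heights (y1) for a mixture of
# H22 (fraction 0.3) and H23 (fraction 0.7).
site	H20	H21	H22	H23	H1263	H1264	H2135	H2136	H2575	y1
rCRS	1	0	0	0	0	0	0	0	0	0.00
16069	0	0	0	0	0	1	0	0	0	0.00
16093	0	1	1	1	1	0	1	1	0	1.00
16126	0	0	0	0	0	1	0	0	1	0.00
16189	0	0	1	0	0	0	1	0	0	0.30
16224	0	0	0	1	0	0	1	1	0	0.68
16293	0	0	1	0	1	0	0	0	0	0.29
16294	0	0	0	0	0	0	0	0	1	0.02
16296	0	0	0	0	0	0	0	0	1	0.00
16304	0	0	0	0	0	0	0	0	1	0.00
16311	0	0	0	1	0	0	1	1	0	0.73
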