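# Curated rCRS (revised Cambridge Reference Sequence, NC_012920) bases at
# commonly reported control-region polymorphic positions. Used to imply the
# transition partner of a bare-number variant and to validate IUPAC ambiguity
# codes against the reference. Positions absent from this table still parse;
# they simply carry no explicit ref/alt annotation.
position	base
16051	A
16069	C
16092	T
16093	T
16111	C
16126	T
16129	G
16145	G
16153	G
16162	A
16172	T
16182	A
16183	A
16189	T
16192	C
16213	G
16217	T
16223	C
16224	T
16232	C
16234	C
16235	A
16239	C
16243	T
16249	T
16256	C
16260	C
16261	C
16264	C
16265	A
16270	C
16274	G
16278	C
16286	C
16290	C
16291	C
16292	C
16293	A
16294	C
16296	C
16298	T
16304	T
16309	A
16311	T
16319	G
16325	T
16327	C
16343	A
16356	T
16362	T
16390	G
16391	G
16399	A
73	A
146	T
150	C
152	T
195	T
263	A
315	C
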