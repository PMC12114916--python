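ribotype	family	29	36	43	56	62	81	94	96	102	111	115	116	118	122	126	130	135	137	138	143	161	171	174	175	177	184	194	198	203	204	208	214	223	225	237	240	243	244	247	252	257	259	262	265	269	277	279	304	307	316
As1	A	C	A	C	G	G	G	C	A	C	T	T	G	T	T	G	A	D	T	C	A	C	T	A	G	G	T	G	C	G	C	G	G	C	C	T	G	C	A	A	C	T	G	G	C	T	A	G	C	D	T
Al/As2	A	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	C	D	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	D	.
Ad2/As3	A	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	D	.	T	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	D	.
As5	A	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	C	D	.	.	.	.	.	.	T	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	D	.
As6	A	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	D	.	T	.	.	.	.	T	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	D	.
B5	B	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	C	D	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	D	.
B6	B	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	D	.	.	.	.	.	.	T	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	D	.
B7	B	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	T	D	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	D	.
D	D	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	C	D	.	.	.	.	C	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	D	.
Aby2	Aby	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	C	D	.	T	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	D	.
Aby3	Aby	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	C	D	C	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	D	.
Aby4	Aby	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	C	D	.	.	.	.	C	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	D	.
Am/Amp	Am	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	C	D	.	.	.	.	.	.	.	T	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	D	.
C-genome-related	C	T	G	T	A	T	A	T	T	T	D	D	.	C	C	A	C	C	.	T	G	A	C	G	A	.	C	T	A	A	T	A	A	T	T	C	T	T	G	G	A	C	T	A	T	G	C	A	D	C	C
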