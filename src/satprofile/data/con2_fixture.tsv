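# family: CON2
# reference: CON2_reference
accession	59	119	179	239	299	358	418	478
CON2_reference	R	C	M	K	W	C	A	Y
D. antarctica KEW-0522816	R	Y	M	K	W	C	A	Y
D. antarctica KEW-0661919	R	Y	M	K	W	C	A	Y
D. antarctica KEW-0521613	R	Y	M	K	W	C	A	Y
D. parvula	R	Y	M	K	W	C	A	Y
D. sukatschewii	G	C	C	T	T	S	R	T
D. cespitosa PI-562652	G	C	C	T	T	S	R	T
D. cespitosa PI-577069	G	C	C	T	T	S	R	T
D. cespitosa PI-371724	G	C	C	T	T	S	R	T
D. elongata	G	C	C	T	T	S	R	T
D. flexuosa	G	C	C	T	T	S	R	T
H. pubescens	G	C	C	T	T	C	A	T
K. macrantha	G	C	C	T	T	C	A	T
D. danthonioides	G	C	C	T	T	S	A	T
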