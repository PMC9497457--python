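gene	modification	role
METTL3	m6A	writer
METTL14	m6A	writer
METTL16	m6A	writer
WTAP	m6A	writer
KIAA1429	m6A	writer
ZC3H13	m6A	writer
RBM15	m6A	writer
RBM15B	m6A	writer
CBLL1	m6A	writer
FTO	m6A	eraser
ALKBH5	m6A	eraser
ALKBH1	m6A	eraser
YTHDC1	m6A	reader
YTHDC2	m6A	reader
YTHDF1	m6A	reader
YTHDF2	m6A	reader
YTHDF3	m6A	reader
HNRNPC	m6A	reader
HNRNPA2B1	m6A	reader
IGF2BP1	m6A	reader
IGF2BP2	m6A	reader
IGF2BP3	m6A	reader
RBMX	m6A	reader
FMR1	m6A	reader
LRPPRC	m6A	reader
ELAVL1	m6A	reader
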