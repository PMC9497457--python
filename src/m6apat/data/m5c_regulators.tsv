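gene	modification	role
NOP2	m5C	writer
NSUN2	m5C	writer
NSUN3	m5C	writer
NSUN4	m5C	writer
NSUN5	m5C	writer
NSUN6	m5C	writer
NSUN7	m5C	writer
DNMT1	m5C	writer
DNMT3A	m5C	writer
DNMT3B	m5C	writer
TET1	m5C	eraser
TET2	m5C	eraser
TET3	m5C	eraser
ALYREF	m5C	reader
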