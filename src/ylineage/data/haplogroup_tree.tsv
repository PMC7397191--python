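E-M96	ROOT	E
D-JST021355	ROOT	D
D1a1a1-N1	D-JST021355	D1a1a1
D1a2a-P47	D-JST021355	D1a2a
C-M130	ROOT	C
C2-M217	C-M130	C2
G-M201	ROOT	G
IJK-M522	ROOT	IJK
IJ-M429	IJK-M522	IJ
I-M170	IJ-M429	I
K-M9	IJK-M522	K
N-M231	K-M9	N
N1a1-M46	N-M231	N1a1
QR-M45	K-M9	QR
O-P186	K-M9	O
O1a-M119	O-P186	O1a
O1b-M268	O-P186	O1b
O1b2-M176	O1b-M268	O1b2
O2-M122	O-P186	O2
O2a1-KL1	O2-M122	O2a1
O2a2-P201	O2-M122	O2a2
O2a2a1a2-M7	O2a2-P201	O2a2a1a2
O2a2b-P164	O2a2-P201	O2a2b
O2a2b1a1-M117	O2a2b-P164	O2a2b1a1
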