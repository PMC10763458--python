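gene	protein	side	direction	km_uM
SLC22A11	OAT4	apical	influx	3779.6
SLC22A12	URAT1	apical	influx	371
SLC2A9	GLUT9	basolateral	efflux	365
SLC22A6	OAT1	basolateral	influx	943
SLC22A7	OAT2	basolateral	influx	1168
SLC22A8	OAT3	basolateral	influx	2888
SLC17A1	NPT1	apical	efflux	1100
SLC17A3	NPT4	apical	efflux
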