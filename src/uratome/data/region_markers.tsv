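region	gene
Podo	NPHS1
Podo	NPHS2
PT	CUBN
PT	LRP2
LOH_DL	AQP1
LOH_DL	SLC14A2
LOH_AL	UMOD
LOH_AL	SLC12A1
DCT	SLC12A3
DCT	TRPM6
CNT	CALB1
CNT	SCNN1G
PC	AQP2
PC	AQP3
ICA	SLC4A1
ICA	KIT
ICB	SLC26A4
ICB	INSRR
EDC	PECAM1
EDC	EMCN
MGC	PDGFRB
MGC	ITGA8
PEC	CLDN1
PEC	CFH
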