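# Reference clone partition of a 91-accession lychee germplasm
# collection (13 clonal groups, 55 grouped samples). Not every
# singleton id is on record, so singletons beyond the known ones are
# synthetic filler ids (FILLxx). Only partition bookkeeping (counts,
# sizes) should be asserted against this file.
group_id	sample_id
G01	SHC2
G01	SHC3
G02	HEL1
G02	HEL2
G03	OH
G03	HKP1
G03	HKP3
G03	HKP4
G03	HKP5
G03	HKP6
G03	HKP7
G03	STHI
G03	KT
G04	KJL1
G04	KJL2
G04	UNK11
G05	SAL1
G05	SAL2
G05	SAL3
G05	NMT4
G05	WC
G06	HL
G06	SSH
G06	KJ
G06	PL
G06	SFHI
G06	SH
G06	KM1
G07	UNK12
G07	NMT5
G08	UNK1
G08	UNK2
G08	UNK3
G08	UNK4
G08	UNK6
G08	NMT1
G09	TM
G09	KMP2
G09	NMT3
G10	UNK10
G10	JF
G11	UNK9
G11	ITO
G12	BRW
G12	HP
G12	PRL
G12	KH1
G13	TS2
G13	CHC
G13	KC
G13	KMM
G13	KSE
G13	KM3
G13	UNK7
G13	UNK8
.	SHC1
.	HKP2
.	KM2
.	KMP1
.	BOS
.	GRF
.	KMN
.	SYH
.	HH
.	NMT2
.	TS1
.	KH2
.	UNK5
.	UNK13
.	FILL01
.	FILL02
.	FILL03
.	FILL04
.	FILL05
.	FILL06
.	FILL07
.	FILL08
.	FILL09
.	FILL10
.	FILL11
.	FILL12
.	FILL13
.	FILL14
.	FILL15
.	FILL16
.	FILL17
.	FILL18
.	FILL19
.	FILL20
.	FILL21
.	FILL22
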