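gene	cluster	functional_category	alias	extra
ABCB1	bile_acid	transport		0
ABCB11	bile_acid	transport	BSEP	0
ABCB4	bile_acid	transport		0
ABCC2	bile_acid	transport	MRP2	0
ABCC3	bile_acid	transport		0
ABCC4	bile_acid	transport		0
ABCG1	bile_acid	transport		0
ABCG5	bile_acid	transport		0
ABCG8	bile_acid	transport		0
ATP8B1	bile_acid	transport		0
SLC10A1	bile_acid	transport	NTCP	0
SLC10A2	bile_acid	transport	ASBT	0
SLCO1A2	bile_acid	transport		0
SLCO1B1	bile_acid	transport	OATP1B1	0
SLCO1B3	bile_acid	transport	OATP1B3	0
SLCO2B1	bile_acid	transport		0
SLC51A	bile_acid	transport	OSTalpha	0
SLC52A	bile_acid	transport	OSTbeta	0
CYP27A1	bile_acid	synthesis_metabolism		0
CYP39A1	bile_acid	synthesis_metabolism		0
CYP3A4	bile_acid	synthesis_metabolism		0
CYP7A1	bile_acid	synthesis_metabolism		0
CYP7B1	bile_acid	synthesis_metabolism		0
CYP8B1	bile_acid	synthesis_metabolism		0
EPHX1	bile_acid	synthesis_metabolism	EPHX	0
HSD3B7	bile_acid	synthesis_metabolism		0
SCP2	bile_acid	synthesis_metabolism		0
AKR1D1	bile_acid	synthesis_metabolism		0
SULT2A1	bile_acid	synthesis_metabolism		0
UGT2B11	bile_acid	synthesis_metabolism		0
FGF19	bile_acid	signaling_regulation		0
FGFR4	bile_acid	signaling_regulation		0
NR1H4	bile_acid	signaling_regulation	FXR	0
HNF1A	bile_acid	signaling_regulation	HNF1alpha	0
NR2A1	bile_acid	signaling_regulation	HNF4alpha	0
NR0B2	bile_acid	signaling_regulation	SHP	0
NR1I2	bile_acid	signaling_regulation	PXR	0
NR1I3	bile_acid	signaling_regulation	CAR	0
NR5A2	bile_acid	signaling_regulation	LRH-1	0
NR2B1	bile_acid	signaling_regulation	RXRalpha	0
KL	bile_acid	signaling_regulation	Klotho-beta	0
BAAT	bile_acid	conjugation		0
SLC27A5	bile_acid	conjugation	BACS	0
CYP1A1	drug_metabolism	phase1		0
CYP1A2	drug_metabolism	phase1		0
CYP2A6	drug_metabolism	phase1		0
CYP2B6	drug_metabolism	phase1		0
CYP2C8	drug_metabolism	phase1		0
CYP2C9	drug_metabolism	phase1		0
CYP2C19	drug_metabolism	phase1		0
CYP2D6	drug_metabolism	phase1		0
CYP2E1	drug_metabolism	phase1		0
CYP3A4	drug_metabolism	phase1		0
TPMT	drug_metabolism	phase1		0
UGT1A1	drug_metabolism	phase2		0
UGT1A4	drug_metabolism	phase2		0
UGT2B7	drug_metabolism	phase2		0
SULT1A1	drug_metabolism	phase2		0
GSTM1	drug_metabolism	phase2		0
GSTP1	drug_metabolism	phase2		0
GSTT1	drug_metabolism	phase2		0
SLC22A1	drug_metabolism	transport	OCT1	0
SLC22A2	drug_metabolism	transport	OCT2	0
SLC22A6	drug_metabolism	transport	OAT1	0
SLC22A7	drug_metabolism	transport	OAT2	0
SLC22A8	drug_metabolism	transport	OAT3	0
SLC47A1	drug_metabolism	transport	MATE1	0
SLCO1A2	drug_metabolism	transport		0
SLCO1B1	drug_metabolism	transport	OATP1B1	0
SLCO1B3	drug_metabolism	transport	OATP1B3	0
SLCO2B1	drug_metabolism	transport		0
ABCB1	drug_metabolism	transport	MDR1	0
ABCC2	drug_metabolism	transport	MRP2	0
ABCG2	drug_metabolism	transport	BCRP	0
HNF1A	drug_metabolism	regulation	HNF1alpha	0
NR2A1	drug_metabolism	regulation	HNF4alpha	0
AHR	drug_metabolism	regulation	AhR	0
NR1I2	drug_metabolism	regulation	PXR	0
NR1I3	drug_metabolism	regulation	CAR	0
NR3C1	drug_metabolism	regulation	GR	0
PPARG	drug_metabolism	regulation	PPARgamma	0
NR2B1	drug_metabolism	regulation	RXRalpha	0
NR3A1	drug_metabolism	regulation	ERalpha	0
NAT2	drug_metabolism	phase2		1
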