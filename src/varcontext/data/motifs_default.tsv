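name	recognition	kind
DpnI	GATC	restriction
DpnII	GATC	restriction
Sau3AI	GATC	restriction
NdeII	GATC	restriction
Bsp143I	GATC	restriction
Asi256I	GATC	restriction
MalI	GATC	restriction
BssMI	GATC	restriction
Lcr047I	GATC	restriction
FaiI	YATR	restriction
MspJI	CNNR	restriction
EcoRI	GAATTC	restriction
BamHI	GGATCC	restriction
HindIII	AAGCTT	restriction
EcoRV	GATATC	restriction
PstI	CTGCAG	restriction
TaqI	TCGA	restriction
HaeIII	GGCC	restriction
AluI	AGCT	restriction
HpaII	CCGG	restriction
SmaI	CCCGGG	restriction
XhoI	CTCGAG	restriction
HinfI	GANTC	restriction
DdeI	CTNAG	restriction
Fnu4HI	GCNGC	restriction
AvaI	CYCGRG	restriction
HincII	GTYRAC	restriction
SpCas9	NGG	pam
SaCas9	NNGRRT	pam
NmCas9	NNNNGATT	pam
St1Cas9	NNAGAAW	pam
St3Cas9	NGGNG	pam
CjCas9	NNNNACA	pam
FnCas9	YG	pam
TdCas9	NAAAW	pam
SpCas9-NG	NG	pam
SpRY	NRN	pam
xCas9	NG	pam
HiFiCas9-HF1	NGG	pam
eSpCas9-1.1	NGG	pam
HypaCas9	NGG	pam
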