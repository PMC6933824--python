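# MitoCarta-style inventory of mitochondria-localized gene products.
# One primary symbol per line, optional comma-separated synonyms.
# Covers the 29 differentially abundant trophoblast proteins plus a margin of
# other genuine MitoCarta entries; deliberately excludes common cytosolic /
# cytoskeletal contaminants (ACTB, GAPDH, TUBB, ...) so they test negative.
ATP5B	ATP5F1B,ATPSB
ATP5A1	ATP5F1A,ATP5A
SDHA	FP,SDH2
NDUFA12	B17.2,DAP13
PCK2	PEPCK2,PEPCK-M
PC	PCB
PDPR
LRPPRC	LRP130,GP130
ACADVL	VLCAD
BCKDHA	MSUD1
BCAT2	BCATM,BCT2
DLD	DLDH,LAD,GCSL
GLDC	GCSP
SLC25A6	ANT3,ANT 3
SLC25A11	OGC,SLC20A4
MAOA
ALDH4A1	P5CDH,ALDH4
HSPD1	HSP60,GROEL
HSPA9	GRP75,MORTALIN,MTHSP75
TRAP1	HSP75,HSP90L
VDAC1	PORIN,VDAC
VDAC2	POR
SOD2	MNSOD,IPOB
PHB	PHB1
HSPA5	GRP78,BIP
HSP90B1	GRP94,TRA1
P4HB	PDI,PDIA1
HSD17B4	MFE2,DBP
CHCHD3	MIC19,MINOS3
NDUFS1	CI-75K
COX4I1	COX4
CS	CITRATE SYNTHASE
TFAM	MTTFA
OPA1	NTG1
MFN1
MFN2	CPRP1
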