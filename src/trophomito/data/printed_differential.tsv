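gene	ratio	log2fc
ATP5B	1.70073	0.766154
ATP5A1	1.509091	0.59368
SDHA	1.615385	0.691878
NDUFA12	2.6	1.378512
PCK2	8	3
PC	2.277778	1.187627
PDPR	2.1	1.070389
LRPPRC	1.846154	0.884523
ACADVL	1.457143	0.543142
BCKDHA	2.5	1.321928
BCAT2	1.8125	0.857981
DLD	1.6	0.678072
GLDC	2.555556	1.353637
SLC25A6	2.052632	1.037475
SLC25A11	2.052632	1.037475
MAOA	1.458564	0.544548
ALDH4A1	1.6	0.678072
HSPD1	1.5	0.584963
HSPA9	1.490196	0.575502
TRAP1	2	1
VDAC1	1.476744	0.56242
VDAC2	1.490566	0.57586
SOD2	2.333333	1.222392
PHB	1.415094	0.500898
HSPA5	0.723077	-0.46778
HSP90B1	0.641892	-0.6396
P4HB	0.738462	-0.43741
HSD17B4	0.658537	-0.60266
CHCHD3	0.478261	-1.06413
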