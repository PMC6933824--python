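gene	pathway
ATP5B	Mitochondrial complex subunits
ATP5A1	Mitochondrial complex subunits
SDHA	Mitochondrial complex subunits
NDUFA12	Mitochondrial complex subunits
PCK2	Carbohydrate metabolism
PC	Carbohydrate metabolism
PDPR	Carbohydrate metabolism
LRPPRC	Fatty acid metabolism
ACADVL	Fatty acid metabolism
BCKDHA	Amino acid metabolism
BCAT2	Amino acid metabolism
DLD	Amino acid metabolism
GLDC	Amino acid metabolism
SLC25A6	Amino acid metabolism
SLC25A11	Amino acid metabolism
MAOA	Amino acid metabolism
ALDH4A1	Amino acid metabolism
HSPD1	Heat shock proteins
HSPA9	Heat shock proteins
TRAP1	Heat shock proteins
VDAC1	VDAC
VDAC2	VDAC
SOD2	Antioxidant
PHB	Mitochondrial aging
HSPA5	Heat shock proteins
HSP90B1	Heat shock proteins
P4HB	Heat shock proteins
HSD17B4	Amino acid metabolism
CHCHD3	Cristae stabilization
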