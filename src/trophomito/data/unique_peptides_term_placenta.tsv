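Protein ID	Gene name	Average unique peptides Cyto-Mito	Average unique peptides Syncytio-Mito
P06576	ATP5B	232	136
P25705	ATP5A1	82	54
P31040	SDHA	41	25
Q9UI09	NDUFA12	12	4
Q16822	PCK2	7	0
P11498	PC	40	17
Q8NCN5	PDPR	20	9
P42704	LRPPRC	71	38
P49748	ACADVL	101	69
P12694	BCKDHA	14	5
O15382	BCAT2	28	15
P09622	DLD	55	34
P23378	GLDC	22	8
P12236	SLC25A6	38	18
Q02978	SLC25A11	38	18
P21397	MAOA	263	180
P30038	ALDH4A1	47	29
P10809	HSPD1	209	139
P38646	HSPA9	75	50
Q12931	TRAP1	23	11
P21796	VDAC1	126	85
P45880	VDAC2	78	52
P04179	SOD2	27	11
P35232	PHB	74	52
P11021	HSPA5	93	129
P14625	HSP90B1	94	147
P07237	P4HB	47	64
P51659	HSD17B4	26	40
Q9NX63	CHCHD3	10	22
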