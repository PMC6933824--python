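stage	gene	ratio	log2fc
first_trimester	ATP5A1	1.618378086	0.69454869
first_trimester	SDHA	1.22129943	0.288416953
first_trimester	NDUFA12	1.725360662	0.786897968
first_trimester	PCK2	4.74273091	2.245718016
first_trimester	PDPR	1.199005005	0.261837681
first_trimester	LRPPRC	1.860274433	0.895515467
first_trimester	BCKDHA	1.845741039	0.884200154
first_trimester	BCAT2	1.54651804	0.629023662
first_trimester	DLD	1.681856344	0.750054482
first_trimester	GLDC	2.443686392	1.28905915
first_trimester	SLC25A11	1.557922844	0.639623785
first_trimester	ALDH4A1	1.093994109	0.12960497
first_trimester	HSPD1	1.092818614	0.128053963
first_trimester	HSPA9	1.811459723	0.857152728
first_trimester	TRAP1	2.513469752	1.329680327
first_trimester	VDAC1	2.07253042	1.051393277
first_trimester	VDAC2	1.282395263	0.358841002
first_trimester	HSPA5	0.541244746	-0.88564697
third_trimester	ATP5B	4.007301263	2.002631
third_trimester	ATP5A1	1.103187599	0.141678
third_trimester	SDHA	1.529047892	0.612634
third_trimester	NDUFA12	1.823551906	0.866751
third_trimester	PC	4.229056657	2.080336
third_trimester	ACADVL	1.795304533	0.844229
third_trimester	BCKDHA	1.347440581	0.430222
third_trimester	BCAT2	81.9494509	6.356662
third_trimester	DLD	3.298492153	1.721807
third_trimester	GLDC	15.15210855	3.921447
third_trimester	SLC25A6	1.490340754	0.575642
third_trimester	SLC25A11	134.4975213	7.071436
third_trimester	ALDH4A1	5.502143902	2.459994
third_trimester	HSPD1	4.451273652	2.154218
third_trimester	HSPA9	6.1607262	2.6231
third_trimester	TRAP1	28.02639676	4.808714
third_trimester	VDAC1	3.102195366	1.63329
third_trimester	VDAC2	1.474975787	0.560691
third_trimester	SOD2	1.799040268	0.847227
third_trimester	HSD17B4	0.470534	-1.08763
third_trimester	CHCHD3	0.649489	-0.62262
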