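Gene	CYT	SYN
ATP5B	389.168	96.36427
ATP5A1	242.5827	219.799
SDHA	25.28696	16.19172
NDUFA12	130.6539	71.19643
PC	3.229057	0
ACADVL	232.9049	129.287
BCKDHA	19.85554	14.47789
BCAT2	80.94945	0
DLD	31.23854	8.77372
GLDC	103.3204	5.884876
SLC25A6	715.1606	479.5348
SLC25A11	133.4975	0
ALDH4A1	12.14576	1.389207
HSPD1	183.9531	40.5506
HSPA9	85.65878	13.06632
TRAP1	157.0878	4.640674
VDAC1	217.4922	69.43148
VDAC2	111.4999	75.27239
SOD2	57.46959	31.50043
HSD17B4	23.51691	51.1044
CHCHD3	38.77691	60.24344
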