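Gene	CYT	SYN
ATP5A1	10.85863	6.709574
SDHA	1.08374	0.887366
NDUFA12	3.312017	1.919608
PCK2	0.171777	0.036219
PDPR	0.043427	0.036219
LRPPRC	1.111726	0.597614
BCKDHA	0.36768	0.199205
BCAT2	0.658157	0.425574
DLD	1.248761	0.74249
GLDC	0.309778	0.126767
SLC25A11	1.438874	0.923585
ALDH4A1	0.673598	0.615723
HSPD1	16.14898	14.77736
HSPA9	4.72387	2.60777
TRAP1	1.365531	0.543285
VDAC1	5.048123	2.435729
VDAC2	2.148179	1.67513
HSPA5	20.69624	38.23823
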