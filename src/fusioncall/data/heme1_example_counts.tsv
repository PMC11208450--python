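Probe set	5	6	8	15	16	22	24	24C	IVS-020
POS_A	36825	34352	29274	36457	34254	21268	17649	35	17068
POS_B	11933	10643	9357	11570	10713	6649	5447	67	5339
POS_C	3254	3014	2613	3199	3095	1884	1555	29	1535
POS_D	778	751	611	735	710	461	353	31	354
POS_E	232	238	189	248	208	147	101	72	128
POS_F	80	50	48	54	51	26	30	12	31
NEG_A	11	14	5	9	4	2	7	52	2
NEG_B	4	4	3	6	7	5	5	16	1
NEG_C	10	5	10	6	6	4	5	76	2
NEG_D	6	1	3	2	6	2	1	39	2
NEG_E	7	5	4	10	6	6	2	43	4
NEG_F	18	19	6	2	9	8	8	27	19
BCR(ex1):ABL1(ex3)	8	9	1	5	8	2	5	27	3
BCR(ex1):JAK2(ex15)	8	11	7	4	5	3	4	30	3
BCR(ex14):ABL1(ex2)	8	6	5	15	5	5	3	64	1
CBFB(ex5):MYH11 (type A)(ex33)	12	23	9	10	8	10	4	24	7
CBFB(ex5):MYH11 (type B)(ex31)	11	11	10	4	4	5	9	48	1
EBF1(ex15):PDGFRB(ex11)	14	15	5	8	3	825	3	10	10
ETV6(ex3):RUNX1(ex3)	15	14	13	8	16	6	12	16	5
ETV6(ex4):JAK2(ex16)	13	10	8	14	5	8	5	27	7
PML(ex6):RARA(ex3)	14	9	9	5	10	5	10	82	44
RBM15(ex1):MKL1(ex4)	14	17	3	249	9	7	2	68	7
RUNX1(ex6):MECOM(ex2)	25	11	11	14	12	5	12	48	7
RUNX1(ex6):RUNX1T1(ex2)	373	20	23	46	9	16	10	45	12
TCF3(ex16):PBX1(ex3)	12	20	3	9	3	24	272	10	19
B2M	31726	71951	10283	30391	4801	65454	8316	34	53889
EEF2	13522	10173	1509	10451	637	10099	2531	36	12455
GUSB	849	1287	134	664	66	778	104	23	2358
PGK1	3603	5680	1302	2293	620	5321	866	27	31558
TBP	143	191	48	273	F	411	67	17	863
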