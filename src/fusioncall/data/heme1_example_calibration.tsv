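# instrument_id: validation-sprint-01
probe_id	role	bg_mean	bg_sd	cut3	cut5	hk_threshold	n	inherited
BCR(ex1):ABL1(ex3)	fusion			21	28			0
BCR(ex1):JAK2(ex15)	fusion			15	21			0
BCR(ex14):ABL1(ex2)	fusion			18	25			0
CBFB(ex5):MYH11 (type A)(ex33)	fusion			21	28			0
CBFB(ex5):MYH11 (type B)(ex31)	fusion			20	29			0
EBF1(ex15):PDGFRB(ex11)	fusion			19	27			0
ETV6(ex3):RUNX1(ex3)	fusion			20	28			0
ETV6(ex4):JAK2(ex16)	fusion			25	35			0
PML(ex6):RARA(ex3)	fusion			22	30			0
RBM15(ex1):MKL1(ex4)	fusion			19	26			0
RUNX1(ex6):MECOM(ex2)	fusion			36	50			0
RUNX1(ex6):RUNX1T1(ex2)	fusion			94	142			0
TCF3(ex16):PBX1(ex3)	fusion			71	104			0
B2M	housekeeping					5316		
EEF2	housekeeping					920		
GUSB	housekeeping					97		
PGK1	housekeeping					683		
TBP	housekeeping					27		
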