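# name: heme1_example
probe_id	kind	fusion_id	tube	lineages
POS_A	pos_control
POS_B	pos_control
POS_C	pos_control
POS_D	pos_control
POS_E	pos_control
POS_F	pos_control
NEG_A	neg_control
NEG_B	neg_control
NEG_C	neg_control
NEG_D	neg_control
NEG_E	neg_control
NEG_F	neg_control
BCR(ex1):ABL1(ex3)	fusion	BCR::ABL1	HEME1	B-ALL;CML
BCR(ex1):JAK2(ex15)	fusion	BCR::JAK2	HEME1	B-ALL
BCR(ex14):ABL1(ex2)	fusion	BCR::ABL1	HEME1	B-ALL;CML
CBFB(ex5):MYH11 (type A)(ex33)	fusion	CBFB::MYH11	HEME1	AML
CBFB(ex5):MYH11 (type B)(ex31)	fusion	CBFB::MYH11	HEME1	AML
EBF1(ex15):PDGFRB(ex11)	fusion	EBF1::PDGFRB	HEME1	B-ALL
ETV6(ex3):RUNX1(ex3)	fusion	ETV6::RUNX1	HEME1	B-ALL
ETV6(ex4):JAK2(ex16)	fusion	ETV6::JAK2	HEME1	B-ALL
PML(ex6):RARA(ex3)	fusion	PML::RARA	HEME1	AML
RBM15(ex1):MKL1(ex4)	fusion	RBM15::MKL1	HEME1	AML
RUNX1(ex6):MECOM(ex2)	fusion	RUNX1::MECOM	HEME1	AML
RUNX1(ex6):RUNX1T1(ex2)	fusion	RUNX1::RUNX1T1	HEME1	AML
TCF3(ex16):PBX1(ex3)	fusion	TCF3::PBX1	HEME1	B-ALL
B2M	housekeeping
EEF2	housekeeping
GUSB	housekeeping
PGK1	housekeeping
TBP	housekeeping
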