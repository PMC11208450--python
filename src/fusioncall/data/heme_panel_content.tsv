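fusion_id	n_probe_sets	association	lineages	n_validation_positives
BCR::ABL1	7	B-ALL or CML	B-ALL;CML	6
BIRC3::MALT	8	Lymphoma	other
CBFA2T3::GLIS2	2	AML (megakaryoblastic)	AML	1
CBFB::MYH11	6	AML	AML	1
DEK::NUP214	1	AML	AML
ETV6::RUNX1	6	B-ALL	B-ALL	1
FIP1L1::PDGFRA	8	Chronic eosinophilic leukemia	other	1
FUS::ERG/FEV	4	AML	AML
IKZF1 deletions	3	CML, Ph-like ALL	CML;B-ALL	6
KAT6A::CREBBP	4	AML	AML	2
KMT2A::xxx	70	infantile leukemia	B-ALL;AML;MPAL	7
MEF2D::xxx	12	B-ALL	B-ALL
NPM1::ALK	1	ALCL	other	1
NPM1::MLF1	1	AML	AML
NUP98::NSD1	2	AML	AML	1
NUP98::xxx	8	T-ALL	T-ALL
NUP214::ABL1	9	B-ALL, T-ALL	B-ALL;T-ALL	1
P2RY8::CRLF2	1	Ph-like B-ALL	B-ALL	3
PAX5::xxx	46	B-ALL	B-ALL	2
PICALM::MLLT10	6	T-ALL	T-ALL	2
PML::RARA	3	AML (promyelocytic)	AML	2
RBM15::MKL1	2	AML (megakaryoblastic)	AML
RUNX1::RUNX1T1	2	AML	AML	1
RUNX1::xxx	7	AML	AML
SET::NUP214	2	AML, T-ALL, B-ALL	AML;T-ALL;B-ALL
TCF3::PBX1	2	B-ALL	B-ALL	1
TCF3/4::xxx	6	B-ALL	B-ALL
xxx::ALK	8	ALCL, histiocytic	other	1
xxx::ABL1/ABL2	35	Ph-like B-ALL, T-ALL	B-ALL;T-ALL	11
xxx::CSF1R	5	Ph-like B-ALL	B-ALL	1
xxx::FGFR1	17	B-ALL, T-ALL, AML	B-ALL;T-ALL;AML
xxx::JAK2	36	Ph-like B-ALL	B-ALL	7
xxx::NOTCH1	4	T-ALL	T-ALL
xxx::NUTM1	6	B-ALL	B-ALL
xxx::PDGFRB	13	Ph-like B-ALL	B-ALL	2
xxx::RARA	12	AML	AML
xxx::RET	3	CMML	other
xxx::ZNF384	16	B-ALL	B-ALL	1
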