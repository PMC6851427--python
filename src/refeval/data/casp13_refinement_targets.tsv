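target_id	residues_included	nres	category	start_model	start_gdt_ha
R0949	43-95, 106-181	129	TBM/FM	TS221_1	49
R0957s2	7-164	158	FM	TS498_1	39
R0959	1-189	189	TBM-hard	TS368_1	45
R0962	2-178	177	TBM-easy	TS246_1	63
R0968s1	6-123	118	FM	TS368_1	45
R0968s2	1-116	116	FM	TS368_3	50
R0974s1	2-70	69	TBM-easy	TS488_1	66
R0976-D1	9-128	120	TBM-easy	TS337_1	69
R0976-D2	129-252	124	TBM-easy	TS337_1	65
R0977-D2	360-563	204	TBM-easy	TS402_3	68
R0979	6-97	92	TBM-hard	TS470_1o	55
R0981-D3	191-393	203	TBM/FM	TS261_1	32
R0981-D4	403-513	111	TBM-hard	TS368_1	45
R0981-D5	514-640	127	TBM-hard	TS116_1	42
R0982-D2	146-277	132	TBM-hard	TS324_1	50
R0986s1	5-92	88	TBM/FM	TS043_4	59
R0986s2	1-155	155	FM	TS043_4	49
R0989-D1	1-134	134	FM	TS432_2	34
R0992	4-110	107	TBM/FM	TS368_1	65
R0993s2	12-109	98	TBM-easy	TS246_1	51
R0996-D4	351-483	133	TBM-easy	TS324_1	53
R0996-D5	484-604	121	TBM-easy	TS324_1	56
R0996-D7	709-848	140	TBM-easy	TS324_1	55
R0997	44-228	185	TBM/FM	TS324_1	42
R0999-D3	866-1045	180	TBM-easy	TS324_1	54
R1001	2-140	139	FM	TS368_1	53
R1002-D2	60-118	59	TBM-easy	TS023_1	66
R1004-D2	152-228	77	TBM-easy	TS324_1	60
R1016	1-203	203	TBM-easy	TS368_1	63
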