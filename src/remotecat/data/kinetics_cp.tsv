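variant	layer	km_mM	km_sd	kcat_s	kcat_sd	eff_1e4	eff_sd	relative_kcat	relative_eff	fold_decrease
Wild-type	-	0.27	0.034	410	20	150	13	1.0	1.0	1.0
D140N	2	1.4	0.45	360	59	29	9.0	0.89	0.19	5.4
Y160F	2	0.53	0.12	120	18	23	3.9	0.30	0.15	6.7
Y160S	2	0.30	0.063	300	50	100	14	0.74	0.65	1.5
Y229F	2	0.33	0.11	150	58	44	11	0.36	0.28	3.5
Y229S	2	0.32	0.025	290	120	92	45	0.72	0.60	1.7
D231A	1	0.15	0.042	0.48	0.10	0.34	0.13	0.0012	0.0022	450
H272L	2	0.93	0.58	4.2	1.8	0.50	0.11	0.010	0.0032	310
H272N	2	0.50	0.16	180	65	36	1.5	0.45	0.24	4.2
C273A	1	0.26	0.063	140	43	56	15	0.35	0.36	2.8
E299D	3	0.22	0.083	120	45	62	34	0.29	0.40	2.5
E299Q	3	0.34	0.11	4.6	1.0	1.4	0.33	0.011	0.0093	110
R57A	1	0.28	0.027	7.5	1.8	2.7	0.73	0.018	0.018	57
S61A	2	0.30	0.036	74	40	25	15	0.18	0.16	6.1
Q104L	3	0.40	0.30	88	36	26	7.5	0.22	0.17	5.9
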