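variant	layer	km_mM	km_sd	kcat_s	kcat_sd	eff_1e4	eff_sd	relative_kcat	relative_eff	fold_decrease
Wild-type	-	0.53	0.055	440	9.2	83	7.8	1.0	1.0	1.0
D140N	2	17	5.9	460	154	3.0	1.7	1.1	0.036	28
Y160F	2	1.0	0.16	110	34	10	2.0	0.24	0.12	8.2
Y160S	2	7.3	2.0	410	160	6.1	3.2	0.94	0.073	14
Y229F	2	0.45	0.11	130	46	31	13	0.30	0.37	2.7
Y229S	2	0.61	0.15	350	170	59	34	0.78	0.71	1.4
D231A	1	0.59	0.33	0.70	0.050	0.14	0.067	0.0016	0.0017	580
H272L	2	0.68	0.28	4.3	0.65	0.71	0.31	0.010	0.0085	120
H272N	2	0.40	0.065	95	45	24	14	0.21	0.29	3.4
C273A	1	0.73	0.35	170	56	26	9.3	0.39	0.31	3.2
E299D	3	0.90	0.17	170	36	20	5.9	0.39	0.24	4.2
E299Q	3	0.33	0.10	5.1	1.0	1.6	0.49	0.012	0.020	51
R57A	1	0.44	0.092	8.2	1.1	1.9	0.39	0.019	0.023	44
S61A	2	0.53	0.18	240	75	46	6.4	0.54	0.56	1.8
Q104L	3	0.81	0.23	52	51	8.0	3.3	0.12	0.096	10
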