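rank	residue	res_num	layer	distance	normalized_score
1	Cys273	273	1	3.0	1.00
2	His272	272	2	5.9	0.49
3	Arg319	319	1	2.7	0.32
4	Tyr229	229	2	7.0	0.32
5	Asp231	231	1	2.6	0.31
6	Asp140	140	2	6.9	0.16
7	Glu299	299	3	8.7	0.12
8	Tyr160	160	2	5.1	0.05
9	Arg106	106	1	2.6	0.04
10	His133	133	1	3.0	0.02
11	His321	321	3	12.3	0.01
12	Arg57	57	1	2.9	0.01
20	Gln136	136	1	3.0	0.00
93	Ser61	61	2	6.5	0.00
170	Gln104	104	3	9.0	0.00
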