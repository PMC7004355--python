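variant	apo	apo_sd	cp	cp_sd	orn	orn_sd	cit	cit_sd
Wild-type	68	1.1	70	0.5	69	0.6	68	0.8
D140N	56	0.3	60	1.0	56	0.3	56	0.2
Y160S	61	0.0	63	0.5	62	0.1	61	0.0
Y160F	69	0.2	71	0.7	70	0.2	69	0.0
Y229F	58	0.1	61	0.6	59	0.2	59	0.1
Y229S	62	2.0	67	0.5	63	0.8	63	1.4
D231A	72	0.3	76	0.6	72	0.3	72	0.5
H272L	51	0.3	52	0.6	52	0.1	53	1.5
H272N	50	0.1	55	0.8	51	0.1	51	0.1
C273A	57	0.5	62	1.1	58	0.2	58	0.2
E299D	58	0.2	61	0.6	59	0.2	58	0.0
E299Q	52	1.3	52	0.2	51	0.5	51	1.9
R57A	73	0.3	74	0.0	74	0.0	74	0.3
S61A	70	0.2	72	0.4	71	0.1	70	0.1
Q104L	67	0.3	69	0.8	68	0.2	68	0.2
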