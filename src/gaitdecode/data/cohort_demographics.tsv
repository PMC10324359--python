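id	age	sex	dd_years	ledd_mg	updrs3_moff	updrs3_mon	rigid_moff	rigid_mon	tremor_moff	tremor_mon	fogq	state_order
sub01	72	M	10	675	47	28	7	3	17	11	10	off/on
sub02	60	F	7	750	47	24	8	3	13	3	20	off
sub03	57	F	5	375	49	24	8	1	10	0	14	off
sub04	66	F	10	513	61	22	5	2	11	4	21	off/on
sub05	53	M	12	1100	79	25	14	5	18	4	24	off
sub06	70	M	12	688	70	37	9	7	20	11	17	on/off
sub07	73	F	9	1439	51	27	9	5	0	0	20	off/on
sub08	67	F	6	500	52	30	9	5	11	3	22	off/on
sub09	59	F	9	700	46	21	10	5	6	3	16	on/off
sub10	78	M	5	550	58	24	12	6	5	3	18	off
sub11	76	M	8	1351	41	11	4	2	3	3	13	off/on
sub12	66	F	15	669	55	8	10	3	11	1	13	on/off
sub13	61	M	7	1150	37	18	10	5	0	0	22	on/off
sub14	67	M	10	913	42	20	10	1	2	4	16	on/off
sub15	66	F	15	925	39	20	7	3	1	0	20	off/on
sub16	67	F	9	1000	27	5	2	1	0	0	15	off/on
sub17	71	F	11	1212	36	19	6	3	6	3	19	on/off
sub18	58	M	11	1263	37	18	8	4	0	0	9	on/off
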