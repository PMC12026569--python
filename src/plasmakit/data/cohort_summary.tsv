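sample_id	gestational_age	ff_percent	snv_acmg	panel_cnv
1	10+4	11	P	none
2	11+5	7	none	none
3	15+2	11	none	none
4	14+0	10	none	dup
5	13+6	9	P	none
6	12+0	8	none	del
7	10+3	11	none	del
8	12+6	14	none	none
9	11+2	10	none	none
10	12+5	5	none	dup
11	10+3	10	P	none
12	13+5	9	P	none
13	11+1	6	none	none
14	12+0	6	P	none
15	11+0	14	none	none
16	13+1	7	none	none
17	12+5	17	VUS	none
18	12+2	14	none	none
19	11+0	11	none	none
20	12+0	5	none	none
21	12+3	7	none	none
22	12+4	7	P	none
23	12+0	5	none	none
24	9+0	10	none	none
25	14+5	10	P	none
26	10+3	8	P	none
27	12+3	5	P	none
28	11+1	12	P	none
29	13+3	20	P	none
30	12+2	6	P	none
31	12+6	11	P	none
32	11+3	12	P	none
33	10+4	9	LP	none
34	11+4	15	P	none
35	12+0	11	P	none
36	12+0	18	P	none
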