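frame	cell_id	parent_id	fate	area	g1
0	1	-1	NB	1.1	0.05
0	2	-1	NB	1.2	0.1
0	3	-1	DIV	1.3	0.15
0	4	-1	NB	1.4	0.2
0	5	-1	NB	1.5	0.25
0	6	-1	NB	1.6	0.3
0	7	-1	NB	1.7	0.35
0	8	-1	NB	1.8	0.4
0	9	-1	NB	1.9	0.45
0	10	-1	NB	2	0.5
1	1	-1	NB	1.1	0.05
1	2	-1	NB	1.2	0.1
1	4	-1	NB	1.4	0.2
1	5	-1	NB	1.5	0.25
1	6	-1	NB	1.6	0.3
1	8	-1	NB	1.8	0.4
1	9	-1	NB	1.9	0.45
1	10	-1	NB	2	0.5
1	7	-1	DEL	0.6	0.35
1	11	3	NB	0.7	0.9
1	12	3	NB	0.7	0.9
2	1	-1	NB	1.1	0.05
2	2	-1	NB	1.2	0.1
2	4	-1	NB	1.4	0.2
2	5	-1	NB	1.5	0.25
2	6	-1	NB	1.6	0.3
2	8	-1	NB	1.8	0.4
2	9	-1	NB	1.9	0.45
2	10	-1	NB	2	0.5
2	11	-1	NB	2.1	0.55
2	12	-1	NB	2.2	0.6
3	1	-1	CENSOR	1.1	0.05
3	2	-1	CENSOR	1.2	0.1
3	4	-1	CENSOR	1.4	0.2
3	5	-1	CENSOR	1.5	0.25
3	6	-1	CENSOR	1.6	0.3
3	8	-1	CENSOR	1.8	0.4
3	9	-1	CENSOR	1.9	0.45
3	10	-1	CENSOR	2	0.5
3	11	-1	CENSOR	2.1	0.55
3	12	-1	CENSOR	2.2	0.6
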