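frame	cell_id_a	cell_id_b
0	1	2
0	2	3
0	3	4
0	4	5
0	6	7
0	7	8
0	8	9
0	9	10
0	1	6
0	2	7
0	3	8
0	4	9
0	5	10
1	1	2
1	2	11
1	11	12
1	4	12
1	4	5
1	6	7
1	7	8
1	8	9
1	9	10
1	1	6
1	2	7
1	8	11
1	8	12
1	4	9
1	5	10
2	1	2
2	2	11
2	11	12
2	4	12
2	4	5
2	6	8
2	8	9
2	9	10
2	1	6
2	2	6
2	8	11
2	8	12
2	4	9
2	5	10
3	1	2
3	2	11
3	11	12
3	4	12
3	4	5
3	6	8
3	8	9
3	9	10
3	1	6
3	2	6
3	8	11
3	8	12
3	4	9
3	5	10
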