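participant_id	lab	n_pos	n_total	call	early_aggregation	repeated
1	A	4	4	positive	false	false
2	A	4	4	positive	false	false
3	A	4	4	positive	false	false
4	A	4	4	positive	false	false
5	A	4	4	positive	false	false
6	A	4	4	positive	false	false
7	A	4	4	positive	false	false
8	A	4	4	positive	false	false
9	A	4	4	positive	false	false
10	A	3	4	positive	false	false
11	A	4	4	positive	false	false
12	A	4	4	positive	false	false
13	A	3	4	positive	false	false
14	A	3	4	positive	false	false
15	A	4	4	positive	false	false
16	A	4	4	positive	false	false
17	A	4	4	positive	false	false
18	A	4	4	positive	false	false
19	A	3	4	positive	false	false
20	A	4	4	positive	false	false
21	A	0	4	negative	false	false
22	A	0	4	negative	false	false
23	A	0	4	negative	false	false
24	A	0	4	negative	false	false
25	A	0	4	negative	false	false
26	A	0	4	negative	false	false
27	A	0	4	negative	false	false
28	A	0	4	negative	false	false
29	A	1	8	negative	false	true
30	A	1	8	negative	false	true
1	B	4	6	positive	false	true
2	B	3	3	positive	false	false
3	B	3	3	positive	false	false
4	B	2	3	positive	false	false
5	B	3	3	positive	false	false
6	B	3	3	positive	false	false
7	B	3	3	positive	false	false
8	B	2	3	positive	false	false
9	B	3	3	positive	false	false
10	B	3	3	positive	false	false
11	B	4	6	positive	false	true
12	B	3	3	positive	false	false
13	B	3	3	positive	false	false
14	B	0	3	negative	false	false
15	B	3	3	positive	false	false
16	B	0	3	negative	false	false
17	B	3	3	positive	false	false
18	B	3	3	positive	false	false
19	B	0	3	negative	false	false
20	B	3	3	positive	false	false
21	B	0	3	negative	false	false
22	B	1	6	negative	false	true
23	B	1	6	negative	false	true
24	B	2	6	positive	false	true
25	B	0	3	negative	false	false
26	B	0	3	negative	false	false
27	B	1	6	negative	false	true
28	B	0	3	negative	false	false
29	B	0	3	negative	false	false
30	B	1	6	negative	false	true
1	C	0	3	negative	false	false
2	C	2	3	positive	false	false
3	C	3	3	positive	false	false
4	C	1	3	inconclusive	false	false
5	C	2	3	positive	false	false
6	C	1	3	inconclusive	false	false
7	C	2	3	positive	false	false
8	C	3	3	positive	false	false
9	C	1	3	inconclusive	false	false
10	C	2	3	positive	false	false
11	C	0	3	negative	false	false
12	C	2	3	positive	false	false
13	C	2	3	positive	false	false
14	C	1	3	inconclusive	false	false
15	C	3	3	positive	false	false
16	C	0	3	negative	false	false
17	C	2	3	positive	false	false
18	C	2	3	positive	false	false
19	C	0	3	negative	false	false
20	C	1	3	inconclusive	false	false
21	C	2	3	positive	false	false
22	C	0	3	negative	false	false
23	C	1	3	inconclusive	false	false
24	C	1	3	inconclusive	false	false
25	C	1	3	inconclusive	false	false
26	C	0	3	negative	false	false
27	C	0	3	negative	false	false
28	C	0	3	negative	false	false
29	C	0	3	negative	false	false
30	C	0	3	negative	false	false
1	D	2	3	positive	false	false
2	D	2	3	positive	false	false
3	D	2	3	positive	false	false
4	D	1	3	inconclusive	false	false
5	D	3	3	positive	false	false
6	D	3	3	positive	false	false
7	D	3	3	positive	false	false
8	D	3	3	positive	false	false
9	D	3	3	positive	false	false
10	D	3	3	positive	false	false
11	D	3	3	positive	false	false
12	D	3	3	positive	false	false
13	D	3	3	positive	false	false
14	D	1	3	negative	false	false
15	D	2	3	positive	false	false
16	D	0	3	negative	false	false
17	D	3	3	positive	false	false
18	D	2	3	inconclusive	true	false
19	D	1	3	negative	false	false
20	D	3	3	positive	false	false
21	D	0	3	negative	false	false
22	D	2	3	inconclusive	true	false
23	D	0	3	negative	false	false
24	D	1	3	inconclusive	false	false
25	D	0	3	negative	false	false
26	D	1	3	negative	false	false
27	D	3	3	inconclusive	true	false
28	D	3	3	positive	false	false
29	D	0	3	negative	false	false
30	D	1	3	negative	false	false
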