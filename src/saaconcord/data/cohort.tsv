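participant_id	group	abeta_status	neuropathology	parkinsonism	fluctuations	vh	rbd	dat_scan
1	DLB	negative	none	present	present	absent	absent	positive
2	DLB	negative	none	present	absent	present	unknown	positive
3	DLB	negative	none	present	present	present	absent	positive
4	DLB	negative	none	present	present	absent	present	positive
5	DLB	negative	none	present	absent	present	present	positive
6	DLB	negative	none	present	absent	absent	unknown	positive
7	DLB	negative	none	present	present	present	present	positive
8	DLB	negative	none	present	present	present	absent	positive
9	DLB	negative	LBD	present	present	present	present	positive
10	DLB	negative	none	present	absent	absent	absent	positive
11	DLB	positive	none	present	unknown	absent	absent	positive
12	DLB	positive	none	present	present	present	present	positive
13	DLB	positive	none	present	absent	absent	absent	positive
14	DLB	positive	none	present	unknown	absent	absent	positive
15	DLB	positive	none	present	present	present	absent	positive
16	DLB	positive	none	absent	absent	present	present	positive
17	DLB	positive	none	present	present	present	absent	positive
18	DLB	positive	LBD_with_AD	present	unknown	absent	present	positive
19	DLB	positive	none	present	present	present	present	positive
20	DLB	positive	none	absent	absent	present	present	positive
21	control	not_applicable	none	unknown	unknown	unknown	unknown	not_applicable
22	control	not_applicable	none	unknown	unknown	unknown	unknown	not_applicable
23	control	not_applicable	none	unknown	unknown	unknown	unknown	not_applicable
24	control	not_applicable	none	unknown	unknown	unknown	unknown	not_applicable
25	control	not_applicable	none	unknown	unknown	unknown	unknown	not_applicable
26	control	not_applicable	none	unknown	unknown	unknown	unknown	not_applicable
27	control	not_applicable	none	unknown	unknown	unknown	unknown	not_applicable
28	control	not_applicable	none	unknown	unknown	unknown	unknown	not_applicable
29	control	not_applicable	none	unknown	unknown	unknown	unknown	not_applicable
30	control	not_applicable	none	unknown	unknown	unknown	unknown	not_applicable
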