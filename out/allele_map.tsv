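pattern	window_first_hb	window_last_hb	allele	source	source_homolog
15	HB-chr1-20	HB-chr1-20	A1	F008	1
16	HB-chr1-20	HB-chr1-20	A1	F008	2
27	HB-chr1-20	HB-chr1-20	A1	F014	1
28	HB-chr1-20	HB-chr1-20	A1	F014	2
100	HB-chr1-20	HB-chr1-20	A1	F050	2
1	HB-chr1-20	HB-chr1-20	A2	F001	1
2	HB-chr1-20	HB-chr1-20	A2	F001	2
3	HB-chr1-20	HB-chr1-20	A2	F002	1
4	HB-chr1-20	HB-chr1-20	A2	F002	2
19	HB-chr1-20	HB-chr1-20	A2	F010	1
20	HB-chr1-20	HB-chr1-20	A2	F010	2
31	HB-chr1-20	HB-chr1-20	A2	F016	1
32	HB-chr1-20	HB-chr1-20	A2	F016	2
45	HB-chr1-20	HB-chr1-20	A2	F023	1
46	HB-chr1-20	HB-chr1-20	A2	F023	2
58	HB-chr1-20	HB-chr1-20	A2	F029	2
97	HB-chr1-20	HB-chr1-20	A2	F049	1
43	HB-chr1-20	HB-chr1-20	A3	F022	1
44	HB-chr1-20	HB-chr1-20	A3	F022	2
7	HB-chr1-20	HB-chr1-20	A4	F004	1
8	HB-chr1-20	HB-chr1-20	A4	F004	2
17	HB-chr1-20	HB-chr1-20	A4	F009	1
18	HB-chr1-20	HB-chr1-20	A4	F009	2
21	HB-chr1-20	HB-chr1-20	A4	F011	1
22	HB-chr1-20	HB-chr1-20	A4	F011	2
49	HB-chr1-20	HB-chr1-20	A4	F025	1
50	HB-chr1-20	HB-chr1-20	A4	F025	2
73	HB-chr1-20	HB-chr1-20	A4	F037	1
9	HB-chr1-20	HB-chr1-20	A5	F005	1
10	HB-chr1-20	HB-chr1-20	A5	F005	2
11	HB-chr1-20	HB-chr1-20	A5	F006	1
12	HB-chr1-20	HB-chr1-20	A5	F006	2
25	HB-chr1-20	HB-chr1-20	A5	F013	1
26	HB-chr1-20	HB-chr1-20	A5	F013	2
29	HB-chr1-20	HB-chr1-20	A5	F015	1
30	HB-chr1-20	HB-chr1-20	A5	F015	2
39	HB-chr1-20	HB-chr1-20	A5	F020	1
40	HB-chr1-20	HB-chr1-20	A5	F020	2
47	HB-chr1-20	HB-chr1-20	A5	F024	1
48	HB-chr1-20	HB-chr1-20	A5	F024	2
13	HB-chr1-20	HB-chr1-20	A6	F007	1
14	HB-chr1-20	HB-chr1-20	A6	F007	2
99	HB-chr1-20	HB-chr1-20	A6	F050	1
5	HB-chr1-20	HB-chr1-20	A7	F003	1
6	HB-chr1-20	HB-chr1-20	A7	F003	2
33	HB-chr1-20	HB-chr1-20	A7	F017	1
34	HB-chr1-20	HB-chr1-20	A7	F017	2
41	HB-chr1-20	HB-chr1-20	A7	F021	1
42	HB-chr1-20	HB-chr1-20	A7	F021	2
57	HB-chr1-20	HB-chr1-20	A7	F029	1
63	HB-chr1-20	HB-chr1-20	A7	F032	1
64	HB-chr1-20	HB-chr1-20	A7	F032	2
98	HB-chr1-20	HB-chr1-20	A7	F049	2
23	HB-chr1-20	HB-chr1-20	A8	F012	1
24	HB-chr1-20	HB-chr1-20	A8	F012	2
35	HB-chr1-20	HB-chr1-20	A8	F018	1
36	HB-chr1-20	HB-chr1-20	A8	F018	2
37	HB-chr1-20	HB-chr1-20	A8	F019	1
38	HB-chr1-20	HB-chr1-20	A8	F019	2
74	HB-chr1-20	HB-chr1-20	A8	F037	2
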