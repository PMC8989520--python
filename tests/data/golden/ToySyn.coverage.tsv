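position_1based	coverage_fraction	start_count	end_count
1	0	0	0
2	0	0	0
3	0	0	0
4	0	0	0
5	0	0	0
6	0	0	0
7	0	0	0
8	0	0	0
9	0	0	0
10	0	0	0
11	0	0	0
12	0	0	0
13	0	0	0
14	0	0	0
15	0	0	0
16	0	0	0
17	0	0	0
18	0	0	0
19	0	0	0
20	0	0	0
21	0	0	0
22	0	0	0
23	0	0	0
24	0	0	0
25	0	0	0
26	0	0	0
27	0	0	0
28	0	0	0
29	0	0	0
30	0	0	0
31	0	0	0
32	0	0	0
33	0	0	0
34	0	0	0
35	0	0	0
36	0	0	0
37	0	0	0
38	0	0	0
39	0	0	0
40	0	0	0
41	0	0	0
42	0	0	0
43	0	0	0
44	0	0	0
45	0	0	0
46	0	0	0
47	0	0	0
48	0	0	0
49	0	0	0
50	0.0333333	0	1
51	0.166667	0	4
52	0.4	0	7
53	0.6	0	6
54	0.9	0	9
55	0.966667	0	2
56	1	0	1
57	1	0	0
58	1	0	0
59	1	0	0
60	1	0	0
61	1	0	0
62	1	0	0
63	1	0	0
64	1	0	0
65	1	0	0
66	1	0	0
67	1	0	0
68	1	0	0
69	1	0	0
70	1	0	0
71	1	0	0
72	1	0	0
73	1	0	0
74	1	0	0
75	1	0	0
76	1	0	0
77	1	0	0
78	1	0	0
79	1	0	0
80	1	0	0
81	1	0	0
82	1	0	0
83	1	0	0
84	1	0	0
85	1	0	0
86	1	0	0
87	1	0	0
88	1	0	0
89	1	0	0
90	1	0	0
91	1	0	0
92	1	30	0
93	0	0	0
94	0	0	0
95	0	0	0
96	0	0	0
97	0	0	0
98	0	0	0
99	0	0	0
100	0	0	0
101	0	0	0
102	0	0	0
103	0	0	0
104	0	0	0
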