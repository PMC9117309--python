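roi_id	name	rsn	x	y	z
1	LH_Vis_1	Vis	-54	43	-15
2	LH_Vis_2	Vis	-56	12	32
3	LH_Vis_3	Vis	-37	-25	-29
4	LH_Vis_4	Vis	-40	58	60
5	LH_Vis_5	Vis	-59	-17	28
6	LH_Vis_6	Vis	-16	57	-32
7	LH_Vis_7	Vis	-21	4	2
8	LH_Vis_8	Vis	-37	-39	-26
9	LH_Vis_9	Vis	-27	-26	13
10	LH_Vis_10	Vis	-47	-16	48
11	LH_Vis_11	Vis	-23	13	60
12	LH_Vis_12	Vis	-29	-6	74
13	LH_Vis_13	Vis	-42	-12	9
14	LH_Vis_14	Vis	-61	55	-28
15	LH_SomMot_1	SomMot	-53	14	-23
16	LH_SomMot_2	SomMot	-56	51	44
17	LH_SomMot_3	SomMot	-22	-13	-24
18	LH_SomMot_4	SomMot	-42	-91	68
19	LH_SomMot_5	SomMot	-62	-100	-26
20	LH_SomMot_6	SomMot	-46	61	-10
21	LH_SomMot_7	SomMot	-36	60	-17
22	LH_SomMot_8	SomMot	-53	10	30
23	LH_SomMot_9	SomMot	-24	59	-7
24	LH_SomMot_10	SomMot	-41	-99	29
25	LH_SomMot_11	SomMot	-22	44	-16
26	LH_SomMot_12	SomMot	-16	-98	63
27	LH_SomMot_13	SomMot	-9	-2	-36
28	LH_SomMot_14	SomMot	-48	48	-19
29	LH_SomMot_15	SomMot	-9	-27	4
30	LH_SomMot_16	SomMot	-59	-43	-33
31	LH_DorsAttn_1	DorsAttn	-18	-46	-29
32	LH_DorsAttn_2	DorsAttn	-36	29	24
33	LH_DorsAttn_3	DorsAttn	-13	54	64
34	LH_DorsAttn_4	DorsAttn	-11	-54	48
35	LH_DorsAttn_5	DorsAttn	-31	-55	-3
36	LH_DorsAttn_6	DorsAttn	-61	-75	11
37	LH_DorsAttn_7	DorsAttn	-13	56	37
38	LH_DorsAttn_8	DorsAttn	-35	25	-17
39	LH_DorsAttn_9	DorsAttn	-36	-8	-32
40	LH_DorsAttn_10	DorsAttn	-10	44	-30
41	LH_DorsAttn_11	DorsAttn	-56	-90	35
42	LH_DorsAttn_12	DorsAttn	-19	31	-31
43	LH_DorsAttn_13	DorsAttn	-57	-38	48
44	LH_SalVentAttn_1	SalVentAttn	-27	-93	22
45	LH_SalVentAttn_2	SalVentAttn	-22	-19	42
46	LH_SalVentAttn_3	SalVentAttn	-45	64	-11
47	LH_SalVentAttn_4	SalVentAttn	-59	-21	14
48	LH_SalVentAttn_5	SalVentAttn	-46	39	-4
49	LH_SalVentAttn_6	SalVentAttn	-33	7	-39
50	LH_SalVentAttn_7	SalVentAttn	-43	-69	23
51	LH_SalVentAttn_8	SalVentAttn	-55	-71	62
52	LH_SalVentAttn_9	SalVentAttn	-58	-4	48
53	LH_SalVentAttn_10	SalVentAttn	-57	-44	-5
54	LH_SalVentAttn_11	SalVentAttn	-47	-99	11
55	LH_SalVentAttn_12	SalVentAttn	-49	-52	-12
56	LH_Limbic_1	Limbic	-10	2	75
57	LH_Limbic_2	Limbic	-43	42	-1
58	LH_Limbic_3	Limbic	-47	-3	62
59	LH_Limbic_4	Limbic	-47	-94	34
60	LH_Limbic_5	Limbic	-31	-15	-24
61	LH_Limbic_6	Limbic	-43	2	60
62	LH_Cont_1	Cont	-29	-18	53
63	LH_Cont_2	Cont	-15	-23	-7
64	LH_Cont_3	Cont	-8	-20	34
65	LH_Cont_4	Cont	-59	57	4
66	LH_Cont_5	Cont	-60	-68	5
67	LH_Cont_6	Cont	-45	-18	33
68	LH_Cont_7	Cont	-50	-16	-36
69	LH_Cont_8	Cont	-12	39	61
70	LH_Cont_9	Cont	-24	11	-5
71	LH_Cont_10	Cont	-52	-89	52
72	LH_Cont_11	Cont	-39	-51	-4
73	LH_Cont_12	Cont	-61	-4	69
74	LH_Cont_13	Cont	-21	-1	57
75	LH_Default_1	Default	-11	-36	41
76	LH_Default_2	Default	-24	-67	-32
77	LH_Default_3	Default	-26	-96	-30
78	LH_Default_4	Default	-60	57	31
79	LH_Default_5	Default	-56	24	24
80	LH_Default_6	Default	-39	57	10
81	LH_Default_7	Default	-12	-41	74
82	LH_Default_8	Default	-37	1	-9
83	LH_Default_9	Default	-55	51	30
84	LH_Default_10	Default	-59	-28	50
85	LH_Default_11	Default	-13	37	47
86	LH_Default_12	Default	-18	-28	43
87	LH_Default_13	Default	-26	11	-36
88	LH_Default_14	Default	-54	-60	20
89	LH_Default_15	Default	-36	-26	-12
90	LH_Default_16	Default	-23	-11	-22
91	LH_Default_17	Default	-52	19	44
92	LH_Default_18	Default	-31	43	16
93	LH_Default_19	Default	-30	18	0
94	LH_Default_20	Default	-16	-40	0
95	LH_Default_21	Default	-9	-78	-36
96	LH_Default_22	Default	-43	-55	4
97	LH_Default_23	Default	-55	-10	-12
98	LH_Default_24	Default	-24	16	28
99	LH_Default_25	Default	-14	-71	14
100	LH_Default_26	Default	-56	38	50
101	RH_Vis_1	Vis	47	-16	53
102	RH_Vis_2	Vis	14	-46	8
103	RH_Vis_3	Vis	49	52	-9
104	RH_Vis_4	Vis	27	-88	44
105	RH_Vis_5	Vis	33	9	68
106	RH_Vis_6	Vis	12	-60	-15
107	RH_Vis_7	Vis	14	-56	43
108	RH_Vis_8	Vis	36	-66	-23
109	RH_Vis_9	Vis	28	33	-6
110	RH_Vis_10	Vis	52	42	17
111	RH_Vis_11	Vis	60	30	15
112	RH_Vis_12	Vis	36	-19	-15
113	RH_Vis_13	Vis	11	-53	-11
114	RH_Vis_14	Vis	55	57	16
115	RH_Vis_15	Vis	53	-28	-30
116	RH_SomMot_1	SomMot	54	-91	-26
117	RH_SomMot_2	SomMot	34	44	68
118	RH_SomMot_3	SomMot	21	-80	-22
119	RH_SomMot_4	SomMot	41	9	62
120	RH_SomMot_5	SomMot	45	35	51
121	RH_SomMot_6	SomMot	50	-21	40
122	RH_SomMot_7	SomMot	36	-89	22
123	RH_SomMot_8	SomMot	15	33	71
124	RH_SomMot_9	SomMot	46	-42	21
125	RH_SomMot_10	SomMot	43	-95	-18
126	RH_SomMot_11	SomMot	51	-27	71
127	RH_SomMot_12	SomMot	57	53	21
128	RH_SomMot_13	SomMot	13	-38	8
129	RH_SomMot_14	SomMot	30	-55	-15
130	RH_SomMot_15	SomMot	43	-65	50
131	RH_SomMot_16	SomMot	56	-71	-25
132	RH_SomMot_17	SomMot	44	48	19
133	RH_SomMot_18	SomMot	47	19	57
134	RH_SomMot_19	SomMot	13	-23	68
135	RH_DorsAttn_1	DorsAttn	19	-94	49
136	RH_DorsAttn_2	DorsAttn	23	37	11
137	RH_DorsAttn_3	DorsAttn	48	6	-31
138	RH_DorsAttn_4	DorsAttn	37	-35	-26
139	RH_DorsAttn_5	DorsAttn	47	41	47
140	RH_DorsAttn_6	DorsAttn	11	53	71
141	RH_DorsAttn_7	DorsAttn	52	-43	43
142	RH_DorsAttn_8	DorsAttn	49	-92	27
143	RH_DorsAttn_9	DorsAttn	14	62	45
144	RH_DorsAttn_10	DorsAttn	24	63	43
145	RH_SalVentAttn_1	SalVentAttn	40	-65	-6
146	RH_SalVentAttn_2	SalVentAttn	42	-39	16
147	RH_SalVentAttn_3	SalVentAttn	58	-16	-16
148	RH_SalVentAttn_4	SalVentAttn	53	-62	-23
149	RH_SalVentAttn_5	SalVentAttn	41	-4	64
150	RH_SalVentAttn_6	SalVentAttn	23	-2	-39
151	RH_SalVentAttn_7	SalVentAttn	27	16	57
152	RH_SalVentAttn_8	SalVentAttn	34	-1	54
153	RH_SalVentAttn_9	SalVentAttn	27	45	50
154	RH_SalVentAttn_10	SalVentAttn	21	-60	-2
155	RH_SalVentAttn_11	SalVentAttn	19	-86	62
156	RH_Limbic_1	Limbic	50	2	44
157	RH_Limbic_2	Limbic	13	-83	64
158	RH_Limbic_3	Limbic	45	-55	-4
159	RH_Limbic_4	Limbic	19	-35	-27
160	RH_Limbic_5	Limbic	62	-66	-31
161	RH_Limbic_6	Limbic	11	63	69
162	RH_Cont_1	Cont	21	-45	-33
163	RH_Cont_2	Cont	43	23	-2
164	RH_Cont_3	Cont	54	-70	69
165	RH_Cont_4	Cont	32	14	20
166	RH_Cont_5	Cont	12	-5	50
167	RH_Cont_6	Cont	16	-73	-10
168	RH_Cont_7	Cont	51	7	57
169	RH_Cont_8	Cont	56	-25	-19
170	RH_Cont_9	Cont	18	-5	0
171	RH_Cont_10	Cont	58	-45	-25
172	RH_Cont_11	Cont	47	-68	-25
173	RH_Cont_12	Cont	44	-51	-24
174	RH_Cont_13	Cont	49	55	-38
175	RH_Cont_14	Cont	46	13	66
176	RH_Cont_15	Cont	57	60	1
177	RH_Cont_16	Cont	13	29	-17
178	RH_Cont_17	Cont	29	6	-9
179	RH_Default_1	Default	14	43	25
180	RH_Default_2	Default	10	9	21
181	RH_Default_3	Default	48	-21	-21
182	RH_Default_4	Default	30	27	57
183	RH_Default_5	Default	21	-79	29
184	RH_Default_6	Default	51	-20	62
185	RH_Default_7	Default	29	-91	56
186	RH_Default_8	Default	60	47	39
187	RH_Default_9	Default	39	0	22
188	RH_Default_10	Default	52	53	-37
189	RH_Default_11	Default	15	-21	45
190	RH_Default_12	Default	23	-59	44
191	RH_Default_13	Default	47	-72	45
192	RH_Default_14	Default	57	64	-5
193	RH_Default_15	Default	56	4	60
194	RH_Default_16	Default	28	26	-5
195	RH_Default_17	Default	60	-69	8
196	RH_Default_18	Default	61	19	5
197	RH_Default_19	Default	35	-66	43
198	RH_Default_20	Default	14	-47	9
199	RH_Default_21	Default	54	31	34
200	RH_Default_22	Default	47	-12	33
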