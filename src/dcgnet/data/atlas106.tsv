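# dcgnet bundled atlas: true 10-region ROI counts, synthetic coordinates
roi_id	roi_name	region	x	y	z
1	Subcortical_1_L	Subcortical	-30.0	60.0	0.0
2	Subcortical_1_R	Subcortical	30.0	60.0	0.0
3	Subcortical_2_L	Subcortical	-32.0	63.0	-3.0
4	Subcortical_2_R	Subcortical	32.0	63.0	-3.0
5	Subcortical_3_L	Subcortical	-34.0	66.0	-6.0
6	Subcortical_3_R	Subcortical	34.0	66.0	-6.0
7	Subcortical_4_L	Subcortical	-36.0	69.0	-9.0
8	Subcortical_4_R	Subcortical	36.0	69.0	-9.0
9	Subcortical_5_L	Subcortical	-38.0	72.0	-12.0
10	Subcortical_5_R	Subcortical	38.0	72.0	-12.0
11	Parietal_1_L	Parietal	-30.0	48.5	35.3
12	Parietal_1_R	Parietal	30.0	48.5	35.3
13	Parietal_2_L	Parietal	-32.0	51.5	32.3
14	Parietal_2_R	Parietal	32.0	51.5	32.3
15	Parietal_3_L	Parietal	-34.0	54.5	29.3
16	Parietal_3_R	Parietal	34.0	54.5	29.3
17	Parietal_4_L	Parietal	-36.0	57.5	26.3
18	Parietal_4_R	Parietal	36.0	57.5	26.3
19	Parietal_5_L	Parietal	-38.0	60.5	23.3
20	Parietal_5_R	Parietal	38.0	60.5	23.3
21	Occipital_1_L	Occipital	-30.0	18.5	57.1
22	Occipital_1_R	Occipital	30.0	18.5	57.1
23	Occipital_2_L	Occipital	-32.0	21.5	54.1
24	Occipital_2_R	Occipital	32.0	21.5	54.1
25	Occipital_3_L	Occipital	-34.0	24.5	51.1
26	Occipital_3_R	Occipital	34.0	24.5	51.1
27	Occipital_4_L	Occipital	-36.0	27.5	48.1
28	Occipital_4_R	Occipital	36.0	27.5	48.1
29	Occipital_5_L	Occipital	-38.0	30.5	45.1
30	Occipital_5_R	Occipital	38.0	30.5	45.1
31	Occipital_6_L	Occipital	-40.0	33.5	42.1
32	Occipital_6_R	Occipital	40.0	33.5	42.1
33	Occipital_7_L	Occipital	-42.0	36.5	39.1
34	Occipital_7_R	Occipital	42.0	36.5	39.1
35	Cerebelum_1_L	Cerebelum	-30.0	-18.5	57.1
36	Cerebelum_1_R	Cerebelum	30.0	-18.5	57.1
37	Cerebelum_2_L	Cerebelum	-32.0	-15.5	54.1
38	Cerebelum_2_R	Cerebelum	32.0	-15.5	54.1
39	Cerebelum_3_L	Cerebelum	-34.0	-12.5	51.1
40	Cerebelum_3_R	Cerebelum	34.0	-12.5	51.1
41	Cerebelum_4_L	Cerebelum	-36.0	-9.5	48.1
42	Cerebelum_4_R	Cerebelum	36.0	-9.5	48.1
43	Cerebelum_5_L	Cerebelum	-38.0	-6.5	45.1
44	Cerebelum_5_R	Cerebelum	38.0	-6.5	45.1
45	Cerebelum_6_L	Cerebelum	-40.0	-3.5	42.1
46	Cerebelum_6_R	Cerebelum	40.0	-3.5	42.1
47	Cerebelum_7_L	Cerebelum	-42.0	-0.5	39.1
48	Cerebelum_7_R	Cerebelum	42.0	-0.5	39.1
49	Cerebelum_8_L	Cerebelum	-44.0	2.5	36.1
50	Cerebelum_8_R	Cerebelum	44.0	2.5	36.1
51	Cerebelum_9_L	Cerebelum	-46.0	5.5	33.1
52	Cerebelum_9_R	Cerebelum	46.0	5.5	33.1
53	Cerebelum_10_L	Cerebelum	-48.0	8.5	30.1
54	Cerebelum_10_R	Cerebelum	48.0	8.5	30.1
55	Frontal_1_L	Frontal	-30.0	-48.5	35.3
56	Frontal_1_R	Frontal	30.0	-48.5	35.3
57	Frontal_2_L	Frontal	-32.0	-45.5	32.3
58	Frontal_2_R	Frontal	32.0	-45.5	32.3
59	Frontal_3_L	Frontal	-34.0	-42.5	29.3
60	Frontal_3_R	Frontal	34.0	-42.5	29.3
61	Frontal_4_L	Frontal	-36.0	-39.5	26.3
62	Frontal_4_R	Frontal	36.0	-39.5	26.3
63	Frontal_5_L	Frontal	-38.0	-36.5	23.3
64	Frontal_5_R	Frontal	38.0	-36.5	23.3
65	Frontal_6_L	Frontal	-40.0	-33.5	20.3
66	Frontal_6_R	Frontal	40.0	-33.5	20.3
67	Frontal_7_L	Frontal	-42.0	-30.5	17.3
68	Frontal_7_R	Frontal	42.0	-30.5	17.3
69	Frontal_8_L	Frontal	-44.0	-27.5	14.3
70	Frontal_8_R	Frontal	44.0	-27.5	14.3
71	Frontal_9_L	Frontal	-46.0	-24.5	11.3
72	Frontal_9_R	Frontal	46.0	-24.5	11.3
73	Frontal_10_L	Frontal	-48.0	-21.5	8.3
74	Frontal_10_R	Frontal	48.0	-21.5	8.3
75	Frontal_11_L	Frontal	-50.0	-18.5	5.3
76	Frontal_11_R	Frontal	50.0	-18.5	5.3
77	Temporal_1_L	Temporal	-30.0	-60.0	0.0
78	Temporal_1_R	Temporal	30.0	-60.0	0.0
79	Temporal_2_L	Temporal	-32.0	-57.0	-3.0
80	Temporal_2_R	Temporal	32.0	-57.0	-3.0
81	Temporal_3_L	Temporal	-34.0	-54.0	-6.0
82	Temporal_3_R	Temporal	34.0	-54.0	-6.0
83	Temporal_4_L	Temporal	-36.0	-51.0	-9.0
84	Temporal_4_R	Temporal	36.0	-51.0	-9.0
85	Limbic_1_L	Limbic	-30.0	-48.5	-35.3
86	Limbic_1_R	Limbic	30.0	-48.5	-35.3
87	Limbic_2_L	Limbic	-32.0	-45.5	-38.3
88	Limbic_2_R	Limbic	32.0	-45.5	-38.3
89	Limbic_3_L	Limbic	-34.0	-42.5	-41.3
90	Limbic_3_R	Limbic	34.0	-42.5	-41.3
91	Limbic_4_L	Limbic	-36.0	-39.5	-44.3
92	Limbic_4_R	Limbic	36.0	-39.5	-44.3
93	Insular_1_L	Insular	-30.0	-18.5	-57.1
94	Insular_1_R	Insular	30.0	-18.5	-57.1
95	Central_1_L	Central	-30.0	18.5	-57.1
96	Central_1_R	Central	30.0	18.5	-57.1
97	Central_2_L	Central	-32.0	21.5	-60.1
98	Central_2_R	Central	32.0	21.5	-60.1
99	Central_3_L	Central	-34.0	24.5	-63.1
100	Central_3_R	Central	34.0	24.5	-63.1
101	Cingulum_1_L	Cingulum	-30.0	48.5	-35.3
102	Cingulum_1_R	Cingulum	30.0	48.5	-35.3
103	Cingulum_2_L	Cingulum	-32.0	51.5	-38.3
104	Cingulum_2_R	Cingulum	32.0	51.5	-38.3
105	Cingulum_3_L	Cingulum	-34.0	54.5	-41.3
106	Cingulum_3_R	Cingulum	34.0	54.5	-41.3
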