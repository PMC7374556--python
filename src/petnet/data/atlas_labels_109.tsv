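label_id	roi_name	is_reference
1	Left Frontal Pole	0
2	Right Frontal Pole	0
3	Left Insular Cortex	0
4	Right Insular Cortex	0
5	Left Superior Frontal Gyrus	0
6	Right Superior Frontal Gyrus	0
7	Left Middle Frontal Gyrus	0
8	Right Middle Frontal Gyrus	0
9	Left Inferior Frontal Gyrus pars triangularis	0
10	Right Inferior Frontal Gyrus pars triangularis	0
11	Left Inferior Frontal Gyrus pars opercularis	0
12	Right Inferior Frontal Gyrus pars opercularis	0
13	Left Precentral Gyrus	0
14	Right Precentral Gyrus	0
15	Left Temporal Pole	0
16	Right Temporal Pole	0
17	Left Superior Temporal Gyrus anterior	0
18	Right Superior Temporal Gyrus anterior	0
19	Left Superior Temporal Gyrus posterior	0
20	Right Superior Temporal Gyrus posterior	0
21	Left Middle Temporal Gyrus anterior	0
22	Right Middle Temporal Gyrus anterior	0
23	Left Middle Temporal Gyrus posterior	0
24	Right Middle Temporal Gyrus posterior	0
25	Left Middle Temporal Gyrus temporooccipital	0
26	Right Middle Temporal Gyrus temporooccipital	0
27	Left Inferior Temporal Gyrus anterior	0
28	Right Inferior Temporal Gyrus anterior	0
29	Left Inferior Temporal Gyrus posterior	0
30	Right Inferior Temporal Gyrus posterior	0
31	Left Inferior Temporal Gyrus temporooccipital	0
32	Right Inferior Temporal Gyrus temporooccipital	0
33	Left Postcentral Gyrus	0
34	Right Postcentral Gyrus	0
35	Left Superior Parietal Lobule	0
36	Right Superior Parietal Lobule	0
37	Left Supramarginal Gyrus anterior	0
38	Right Supramarginal Gyrus anterior	0
39	Left Supramarginal Gyrus posterior	0
40	Right Supramarginal Gyrus posterior	0
41	Left Angular Gyrus	0
42	Right Angular Gyrus	0
43	Left Lateral Occipital Cortex superior	0
44	Right Lateral Occipital Cortex superior	0
45	Left Lateral Occipital Cortex inferior	0
46	Right Lateral Occipital Cortex inferior	0
47	Left Intracalcarine Cortex	0
48	Right Intracalcarine Cortex	0
49	Left Frontal Medial Cortex	0
50	Right Frontal Medial Cortex	0
51	Left Juxtapositional Lobule	0
52	Right Juxtapositional Lobule	0
53	Left Subcallosal Cortex	0
54	Right Subcallosal Cortex	0
55	Left Paracingulate Gyrus	0
56	Right Paracingulate Gyrus	0
57	Left Cingulate Gyrus anterior	0
58	Right Cingulate Gyrus anterior	0
59	Left Cingulate Gyrus posterior	0
60	Right Cingulate Gyrus posterior	0
61	Left Precuneous Cortex	0
62	Right Precuneous Cortex	0
63	Left Cuneal Cortex	0
64	Right Cuneal Cortex	0
65	Left Frontal Orbital Cortex	0
66	Right Frontal Orbital Cortex	0
67	Left Parahippocampal Gyrus anterior	0
68	Right Parahippocampal Gyrus anterior	0
69	Left Parahippocampal Gyrus posterior	0
70	Right Parahippocampal Gyrus posterior	0
71	Left Lingual Gyrus	0
72	Right Lingual Gyrus	0
73	Left Temporal Fusiform Cortex anterior	0
74	Right Temporal Fusiform Cortex anterior	0
75	Left Temporal Fusiform Cortex posterior	0
76	Right Temporal Fusiform Cortex posterior	0
77	Left Temporal Occipital Fusiform Cortex	0
78	Right Temporal Occipital Fusiform Cortex	0
79	Left Occipital Fusiform Gyrus	0
80	Right Occipital Fusiform Gyrus	0
81	Left Frontal Operculum Cortex	0
82	Right Frontal Operculum Cortex	0
83	Left Central Opercular Cortex	0
84	Right Central Opercular Cortex	0
85	Left Parietal Operculum Cortex	0
86	Right Parietal Operculum Cortex	0
87	Left Planum Polare	0
88	Right Planum Polare	0
89	Left Heschl's Gyrus	0
90	Right Heschl's Gyrus	0
91	Left Planum Temporale	0
92	Right Planum Temporale	0
93	Left Supracalcarine Cortex	0
94	Right Supracalcarine Cortex	0
95	Left Occipital Pole	0
96	Right Occipital Pole	0
97	Left Thalamus	0
98	Right Thalamus	0
99	Left Caudate	0
100	Right Caudate	0
101	Left Putamen	0
102	Right Putamen	0
103	Left Hippocampus	0
104	Right Hippocampus	0
105	Left Amygdala	0
106	Right Amygdala	0
107	Left Accumbens	0
108	Right Accumbens	0
109	Brainstem	0
110	Left Cerebellum	1
111	Right Cerebellum	1
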