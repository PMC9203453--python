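region_id,name,cx,cy,cz,level2_parent,level1_parent
1,Precentral_L,-39,-6,51,Frontal_L,Cerebrum_L
2,Precentral_R,39,-6,51,Frontal_R,Cerebrum_R
3,Frontal_Sup_L,-22,35,42,Frontal_L,Cerebrum_L
4,Frontal_Sup_R,22,35,42,Frontal_R,Cerebrum_R
5,Frontal_Sup_Orb_L,-17,48,-14,Frontal_L,Cerebrum_L
6,Frontal_Sup_Orb_R,17,48,-14,Frontal_R,Cerebrum_R
7,Frontal_Mid_L,-34,33,34,Frontal_L,Cerebrum_L
8,Frontal_Mid_R,34,33,34,Frontal_R,Cerebrum_R
9,Frontal_Mid_Orb_L,-31,50,-10,Frontal_L,Cerebrum_L
10,Frontal_Mid_Orb_R,31,50,-10,Frontal_R,Cerebrum_R
11,Frontal_Inf_Oper_L,-49,15,21,Frontal_L,Cerebrum_L
12,Frontal_Inf_Oper_R,49,15,21,Frontal_R,Cerebrum_R
13,Frontal_Inf_Tri_L,-47,30,14,Frontal_L,Cerebrum_L
14,Frontal_Inf_Tri_R,47,30,14,Frontal_R,Cerebrum_R
15,Frontal_Inf_Orb_L,-38,31,-12,Frontal_L,Cerebrum_L
16,Frontal_Inf_Orb_R,38,31,-12,Frontal_R,Cerebrum_R
17,Rolandic_Oper_L,-49,-8,14,Frontal_L,Cerebrum_L
18,Rolandic_Oper_R,49,-8,14,Frontal_R,Cerebrum_R
19,Supp_Motor_Area_L,-6,5,61,Frontal_L,Cerebrum_L
20,Supp_Motor_Area_R,6,5,61,Frontal_R,Cerebrum_R
21,Olfactory_L,-9,15,-12,Limbic_L,Cerebrum_L
22,Olfactory_R,9,15,-12,Limbic_R,Cerebrum_R
23,Frontal_Sup_Medial_L,-6,49,31,Frontal_L,Cerebrum_L
24,Frontal_Sup_Medial_R,6,49,31,Frontal_R,Cerebrum_R
25,Frontal_Med_Orb_L,-6,54,-7,Frontal_L,Cerebrum_L
26,Frontal_Med_Orb_R,6,54,-7,Frontal_R,Cerebrum_R
27,Rectus_L,-6,37,-18,Frontal_L,Cerebrum_L
28,Rectus_R,6,37,-18,Frontal_R,Cerebrum_R
29,Insula_L,-36,7,3,Sublobar_L,Cerebrum_L
30,Insula_R,36,7,3,Sublobar_R,Cerebrum_R
31,Cingulum_Ant_L,-5,35,14,Limbic_L,Cerebrum_L
32,Cingulum_Ant_R,5,35,14,Limbic_R,Cerebrum_R
33,Cingulum_Mid_L,-6,-15,42,Limbic_L,Cerebrum_L
34,Cingulum_Mid_R,6,-15,42,Limbic_R,Cerebrum_R
35,Cingulum_Post_L,-6,-43,25,Limbic_L,Cerebrum_L
36,Cingulum_Post_R,6,-43,25,Limbic_R,Cerebrum_R
37,Hippocampus_L,-26,-21,-10,Limbic_L,Cerebrum_L
38,Hippocampus_R,26,-21,-10,Limbic_R,Cerebrum_R
39,ParaHippocampal_L,-24,-16,-21,Limbic_L,Cerebrum_L
40,ParaHippocampal_R,24,-16,-21,Limbic_R,Cerebrum_R
41,Amygdala_L,-24,-1,-17,Limbic_L,Cerebrum_L
42,Amygdala_R,24,-1,-17,Limbic_R,Cerebrum_R
43,Calcarine_L,-9,-79,6,Occipital_L,Cerebrum_L
44,Calcarine_R,9,-79,6,Occipital_R,Cerebrum_R
45,Cuneus_L,-7,-80,27,Occipital_L,Cerebrum_L
46,Cuneus_R,7,-80,27,Occipital_R,Cerebrum_R
47,Lingual_L,-15,-68,-5,Occipital_L,Cerebrum_L
48,Lingual_R,15,-68,-5,Occipital_R,Cerebrum_R
49,Occipital_Sup_L,-18,-84,28,Occipital_L,Cerebrum_L
50,Occipital_Sup_R,18,-84,28,Occipital_R,Cerebrum_R
51,Occipital_Mid_L,-33,-81,16,Occipital_L,Cerebrum_L
52,Occipital_Mid_R,33,-81,16,Occipital_R,Cerebrum_R
53,Occipital_Inf_L,-37,-82,-8,Occipital_L,Cerebrum_L
54,Occipital_Inf_R,37,-82,-8,Occipital_R,Cerebrum_R
55,Fusiform_L,-32,-40,-20,Temporal_L,Cerebrum_L
56,Fusiform_R,32,-40,-20,Temporal_R,Cerebrum_R
57,Postcentral_L,-43,-23,49,Parietal_L,Cerebrum_L
58,Postcentral_R,43,-23,49,Parietal_R,Cerebrum_R
59,Parietal_Sup_L,-24,-60,59,Parietal_L,Cerebrum_L
60,Parietal_Sup_R,24,-60,59,Parietal_R,Cerebrum_R
61,Parietal_Inf_L,-44,-46,47,Parietal_L,Cerebrum_L
62,Parietal_Inf_R,44,-46,47,Parietal_R,Cerebrum_R
63,SupraMarginal_L,-56,-34,30,Parietal_L,Cerebrum_L
64,SupraMarginal_R,56,-34,30,Parietal_R,Cerebrum_R
65,Angular_L,-45,-61,36,Parietal_L,Cerebrum_L
66,Angular_R,45,-61,36,Parietal_R,Cerebrum_R
67,Precuneus_L,-8,-56,48,Parietal_L,Cerebrum_L
68,Precuneus_R,8,-56,48,Parietal_R,Cerebrum_R
69,Paracentral_Lobule_L,-6,-25,70,Parietal_L,Cerebrum_L
70,Paracentral_Lobule_R,6,-25,70,Parietal_R,Cerebrum_R
71,Caudate_L,-12,11,9,Sublobar_L,Cerebrum_L
72,Caudate_R,12,11,9,Sublobar_R,Cerebrum_R
73,Putamen_L,-25,4,2,Sublobar_L,Cerebrum_L
74,Putamen_R,25,4,2,Sublobar_R,Cerebrum_R
75,Pallidum_L,-19,0,0,Sublobar_L,Cerebrum_L
76,Pallidum_R,19,0,0,Sublobar_R,Cerebrum_R
77,Thalamus_L,-12,-18,8,Sublobar_L,Cerebrum_L
78,Thalamus_R,12,-18,8,Sublobar_R,Cerebrum_R
79,Heschl_L,-43,-19,10,Temporal_L,Cerebrum_L
80,Heschl_R,43,-19,10,Temporal_R,Cerebrum_R
81,Temporal_Sup_L,-55,-21,7,Temporal_L,Cerebrum_L
82,Temporal_Sup_R,55,-21,7,Temporal_R,Cerebrum_R
83,Temporal_Pole_Sup_L,-41,15,-20,Temporal_L,Cerebrum_L
84,Temporal_Pole_Sup_R,41,15,-20,Temporal_R,Cerebrum_R
85,Temporal_Mid_L,-57,-34,-2,Temporal_L,Cerebrum_L
86,Temporal_Mid_R,57,-34,-2,Temporal_R,Cerebrum_R
87,Temporal_Pole_Mid_L,-39,15,-32,Temporal_L,Cerebrum_L
88,Temporal_Pole_Mid_R,39,15,-32,Temporal_R,Cerebrum_R
89,Temporal_Inf_L,-52,-31,-23,Temporal_L,Cerebrum_L
90,Temporal_Inf_R,52,-31,-23,Temporal_R,Cerebrum_R
91,Cerebelum_Crus1_L,-38,-67,-30,Cerebellum_Post_L,Cerebellum_L
92,Cerebelum_Crus1_R,38,-67,-30,Cerebellum_Post_R,Cerebellum_R
93,Cerebelum_Crus2_L,-32,-69,-40,Cerebellum_Post_L,Cerebellum_L
94,Cerebelum_Crus2_R,32,-69,-40,Cerebellum_Post_R,Cerebellum_R
95,Cerebelum_3_L,-9,-34,-19,Cerebellum_Ant_L,Cerebellum_L
96,Cerebelum_3_R,9,-34,-19,Cerebellum_Ant_R,Cerebellum_R
97,Cerebelum_4_5_L,-15,-43,-17,Cerebellum_Ant_L,Cerebellum_L
98,Cerebelum_4_5_R,15,-43,-17,Cerebellum_Ant_R,Cerebellum_R
99,Cerebelum_6_L,-24,-59,-22,Cerebellum_Post_L,Cerebellum_L
100,Cerebelum_6_R,24,-59,-22,Cerebellum_Post_R,Cerebellum_R
101,Cerebelum_7b_L,-27,-60,-45,Cerebellum_Post_L,Cerebellum_L
102,Cerebelum_7b_R,27,-60,-45,Cerebellum_Post_R,Cerebellum_R
103,Cerebelum_8_L,-26,-56,-49,Cerebellum_Post_L,Cerebellum_L
104,Cerebelum_8_R,26,-56,-49,Cerebellum_Post_R,Cerebellum_R
105,Cerebelum_9_L,-11,-49,-46,Cerebellum_Post_L,Cerebellum_L
106,Cerebelum_9_R,11,-49,-46,Cerebellum_Post_R,Cerebellum_R
107,Cerebelum_10_L,-23,-34,-41,Cerebellum_Post_L,Cerebellum_L
108,Cerebelum_10_R,23,-34,-41,Cerebellum_Post_R,Cerebellum_R
109,Vermis_1_2,0,-39,-20,Vermis_Ant,Midline
110,Vermis_3,0,-40,-11,Vermis_Ant,Midline
111,Vermis_4_5,0,-52,-6,Vermis_Ant,Midline
112,Vermis_6,0,-67,-15,Vermis_Post,Midline
113,Vermis_7,0,-72,-25,Vermis_Post,Midline
114,Vermis_8,0,-64,-34,Vermis_Post,Midline
115,Vermis_9,0,-55,-35,Vermis_Post,Midline
116,Vermis_10,0,-46,-32,Vermis_Post,Midline
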