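roi_index,label,hemisphere,lobe_group,centroid_x_mm,centroid_y_mm,centroid_z_mm
1,Precentral_L,L,Cntr-Prtl,-39,-6,51
2,Precentral_R,R,Cntr-Prtl,39,-6,51
3,Frontal_Sup_L,L,Front,-18,35,42
4,Frontal_Sup_R,R,Front,18,35,42
5,Frontal_Sup_Orb_L,L,Front,-17,47,-13
6,Frontal_Sup_Orb_R,R,Front,17,47,-13
7,Frontal_Mid_L,L,Front,-33,33,35
8,Frontal_Mid_R,R,Front,33,33,35
9,Frontal_Mid_Orb_L,L,Front,-31,50,-10
10,Frontal_Mid_Orb_R,R,Front,31,50,-10
11,Frontal_Inf_Oper_L,L,Front,-48,13,19
12,Frontal_Inf_Oper_R,R,Front,48,13,19
13,Frontal_Inf_Tri_L,L,Front,-46,30,14
14,Frontal_Inf_Tri_R,R,Front,46,30,14
15,Frontal_Inf_Orb_L,L,Front,-36,31,-12
16,Frontal_Inf_Orb_R,R,Front,36,31,-12
17,Rolandic_Oper_L,L,Cntr-Prtl,-47,-8,14
18,Rolandic_Oper_R,R,Cntr-Prtl,47,-8,14
19,Supp_Motor_Area_L,L,Cntr-Prtl,-6,5,61
20,Supp_Motor_Area_R,R,Cntr-Prtl,6,5,61
21,Olfactory_L,L,Front,-8,15,-11
22,Olfactory_R,R,Front,8,15,-11
23,Frontal_Sup_Medial_L,L,Front,-5,49,31
24,Frontal_Sup_Medial_R,R,Front,5,49,31
25,Frontal_Med_Orb_L,L,Front,-5,54,-7
26,Frontal_Med_Orb_R,R,Front,5,54,-7
27,Rectus_L,L,Front,-5,37,-18
28,Rectus_R,R,Front,5,37,-18
29,Insula_L,L,Front,-35,7,3
30,Insula_R,R,Front,35,7,3
31,Cingulum_Ant_L,L,Front,-4,35,14
32,Cingulum_Ant_R,R,Front,4,35,14
33,Cingulum_Mid_L,L,Cntr-Prtl,-5,-15,42
34,Cingulum_Mid_R,R,Cntr-Prtl,5,-15,42
35,Cingulum_Post_L,L,Cntr-Prtl,-5,-43,25
36,Cingulum_Post_R,R,Cntr-Prtl,5,-43,25
37,Hippocampus_L,L,Tmp,-25,-21,-10
38,Hippocampus_R,R,Tmp,25,-21,-10
39,ParaHippocampal_L,L,Tmp,-21,-16,-21
40,ParaHippocampal_R,R,Tmp,21,-16,-21
41,Amygdala_L,L,Tmp,-23,-1,-17
42,Amygdala_R,R,Tmp,23,-1,-17
43,Calcarine_L,L,Occp,-7,-79,6
44,Calcarine_R,R,Occp,7,-79,6
45,Cuneus_L,L,Occp,-6,-80,27
46,Cuneus_R,R,Occp,6,-80,27
47,Lingual_L,L,Occp,-15,-68,-5
48,Lingual_R,R,Occp,15,-68,-5
49,Occipital_Sup_L,L,Occp,-17,-84,28
50,Occipital_Sup_R,R,Occp,17,-84,28
51,Occipital_Mid_L,L,Occp,-32,-81,16
52,Occipital_Mid_R,R,Occp,32,-81,16
53,Occipital_Inf_L,L,Occp,-36,-78,-8
54,Occipital_Inf_R,R,Occp,36,-78,-8
55,Fusiform_L,L,Tmp,-31,-40,-20
56,Fusiform_R,R,Tmp,31,-40,-20
57,Postcentral_L,L,Cntr-Prtl,-42,-23,49
58,Postcentral_R,R,Cntr-Prtl,42,-23,49
59,Parietal_Sup_L,L,Cntr-Prtl,-23,-60,59
60,Parietal_Sup_R,R,Cntr-Prtl,23,-60,59
61,Parietal_Inf_L,L,Cntr-Prtl,-43,-46,47
62,Parietal_Inf_R,R,Cntr-Prtl,43,-46,47
63,SupraMarginal_L,L,Cntr-Prtl,-56,-34,30
64,SupraMarginal_R,R,Cntr-Prtl,56,-34,30
65,Angular_L,L,Cntr-Prtl,-44,-61,36
66,Angular_R,R,Cntr-Prtl,44,-61,36
67,Precuneus_L,L,Cntr-Prtl,-7,-56,48
68,Precuneus_R,R,Cntr-Prtl,7,-56,48
69,Paracentral_Lobule_L,L,Cntr-Prtl,-8,-25,70
70,Paracentral_Lobule_R,R,Cntr-Prtl,8,-25,70
71,Caudate_L,L,Subcort,-11,11,9
72,Caudate_R,R,Subcort,11,11,9
73,Putamen_L,L,Subcort,-24,4,2
74,Putamen_R,R,Subcort,24,4,2
75,Pallidum_L,L,Subcort,-18,0,0
76,Pallidum_R,R,Subcort,18,0,0
77,Thalamus_L,L,Subcort,-11,-18,8
78,Thalamus_R,R,Subcort,11,-18,8
79,Heschl_L,L,Tmp,-42,-19,10
80,Heschl_R,R,Tmp,42,-19,10
81,Temporal_Sup_L,L,Tmp,-53,-21,7
82,Temporal_Sup_R,R,Tmp,53,-21,7
83,Temporal_Pole_Sup_L,L,Tmp,-40,15,-20
84,Temporal_Pole_Sup_R,R,Tmp,40,15,-20
85,Temporal_Mid_L,L,Tmp,-56,-34,-2
86,Temporal_Mid_R,R,Tmp,56,-34,-2
87,Temporal_Pole_Mid_L,L,Tmp,-36,15,-34
88,Temporal_Pole_Mid_R,R,Tmp,36,15,-34
89,Temporal_Inf_L,L,Tmp,-50,-28,-23
90,Temporal_Inf_R,R,Tmp,50,-28,-23
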