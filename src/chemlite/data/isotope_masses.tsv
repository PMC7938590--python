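# Monoisotopic (most abundant isotope) masses, Da; one row per element.
# Columns: atomic_number, symbol, monoisotopic_mass. A mass of 0 means
# no stable/most-common isotope mass is tabulated for that element.
atomic_number	symbol	mass
1	H	1.007825032
2	He	4.002603254
3	Li	7.016004550
4	Be	9.012182200
5	B	11.009305400
6	C	12.000000000
7	N	14.003074000
8	O	15.994914620
9	F	18.998403220
10	Ne	19.992440180
11	Na	22.989769280
12	Mg	23.985041700
13	Al	26.981538630
14	Si	27.976926530
15	P	30.973761630
16	S	31.972071000
17	Cl	34.968852680
18	Ar	39.962383120
19	K	38.963706680
20	Ca	39.962590980
21	Sc	44.955911900
22	Ti	47.947946300
23	V	50.943959500
24	Cr	51.940507500
25	Mn	54.938045100
26	Fe	55.934937500
27	Co	58.933195000
28	Ni	57.935342900
29	Cu	62.929597500
30	Zn	63.929142200
31	Ga	68.925573600
32	Ge	73.921177800
33	As	74.921596500
34	Se	79.916521300
35	Br	78.918337100
36	Kr	83.911507000
37	Rb	84.911789740
38	Sr	87.905612100
39	Y	88.905848300
40	Zr	89.904704400
41	Nb	92.906378100
42	Mo	97.905408200
43	Tc	96.906365000
44	Ru	101.904349300
45	Rh	102.905504000
46	Pd	105.903486000
47	Ag	106.905097000
48	Cd	113.903358500
49	In	114.903878000
50	Sn	119.902194700
51	Sb	120.903815700
52	Te	129.906224400
53	I	126.904473000
54	Xe	131.904153500
55	Cs	132.905451900
56	Ba	137.905247200
57	La	138.906353300
58	Ce	139.905438700
59	Pr	140.907652800
60	Nd	141.907723300
61	Pm	144.912749000
62	Sm	151.919732400
63	Eu	152.921230300
64	Gd	157.924103900
65	Tb	158.925346800
66	Dy	163.929174800
67	Ho	164.930322100
68	Er	165.930293100
69	Tm	168.934213300
70	Yb	173.938862100
71	Lu	174.940771800
72	Hf	179.946550000
73	Ta	180.947995800
74	W	183.950931200
75	Re	186.955753100
76	Os	191.961480700
77	Ir	192.962926400
78	Pt	194.964791100
79	Au	196.966568700
80	Hg	201.970643000
81	Tl	204.974427500
82	Pb	207.976652100
83	Bi	208.980398700
84	Po	208.982430400
85	At	209.987148000
86	Rn	222.017570600
87	Fr	223.019735900
88	Ra	226.025402600
89	Ac	227.027752100
90	Th	232.038055300
91	Pa	231.035884000
92	U	238.050788200
93	Np	236.046570000
94	Pu	238.049559900
95	Am	241.056829100
96	Cm	243.061389100
97	Bk	247.070307000
98	Cf	249.074853500
99	Es	252.082980000
100	Fm	257.095105000
101	Md	258.098431000
102	No	259.101030000
103	Lr	262.109630000
104	Rf	267.121530000
105	Db	268.125450000
106	Sg	271.133470000
107	Bh	270.133620000
108	Hs	269.134060000
109	Mt	278.154810000
110	Ds	281.162060000
111	Rg	281.165370000
112	Cn	285.174110000
113	Nh	284.178730000
114	Fl	289.190420000
115	Mc	288.192740000
116	Lv	293.204490000
117	Ts	292.207460000
118	Og	294.213920000
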