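number,locality,species,n,n_infected,data_source,haplotypes
1,Fish Lake,L. samuelis,20,20,Present,A1:14
2,Eau Claire,L. samuelis,22,21,Present,A1:2;A8:1
3,Black River,L. samuelis,17,17,Present,A1:14
4,Fort McCoy,L. samuelis,23,23,Present,A1:20;A10:1
5,Indiana Dunes,L. samuelis,21,1,Present,
6,Allegan,L. samuelis,30,0,Present,
7,Saratoga Spr.s,L. samuelis,27,0,Present,
8,Fall Cr,L. anna,20,20,G,C1:11
9,Yuba Gap,L. anna,20,20,G,C1:14;J1:1
10,Castle Pk,L. anna,18,16,G,C1:9
11,Donner Pass,L. anna,18,17,G,C1:4
12,Marlette Lk,L. anna,19,19,Present,C1:9
13,Leek Spr.s,L. anna,20,20,G,C1:18
14,Cottonwood,L. idas,25,25,Present,A2:24
15,White Mt.,L. idas,24,24,Present,A2:15
16,StrawB Mt.s,L. idas,20,20,G,A2:17
17,Siyeh Cr,L. idas,20,20,G,A2:14
18,Soldier Cr,L. idas,20,19,G,A2:12
19,Tibbs Butte,L. idas,20,20,G,A2:17
20,King’s Hill,L. idas,18,18,G,A2:12
21,Garnet Pk,L. idas,20,19,G,A2:5;A12:1;B1:2
22,Shook Mtn,L. idas,28,28,Present,A2:13;A13:4;A15:1
23,Wolftone Rd,L. idas,4,4,Present,A2:3;A13:1
24,Bunsen Pk,L. idas,20,19,G,A2:11
25,Hayden V,L. idas,22,22,G,A2:11;B1:1
26,Animas RH,L. idas,13,13,G,A1:6;A2:2
27,Red Mt. P,L. idas,4,4,G,A1:1;A2:1
28,Tomboy Rd,L. idas,24,24,G,A1:12
29,Nolan Rd,L. idas,8,8,Present,
30,Spruce Barley,L. idas,20,20,Present,A2:1;B1:1
31,Tok,L. idas,14,14,Present,A2:2
32,Tolovana Cr,L. idas,9,9,Present,A2:1;A13:1;A15:1
33,Soda Mt.,L. ricei,20,19,G,A2:12
34,Rainy Pass,L. ricei,20,20,Present,A2:12;A17:3
35,Chinook Pass,L. ricei,25,25,Present,A2:17
36,Big Lk,L. ricei,20,20,G,A2:10;A3:1;A4:1;B1:5
37,Cave Lk,L. ricei,24,24,G,A1:1;A2:20
38,Marble Mts.,L. ricei,12,7,G,C1:5;G1:1;G2:1
39,Shovel Cr,L. ricei,21,20,G,C1:15;C3:1
40,Beulah,L. melissa-East,10,10,Present,A1:1
41,Brandon,L. melissa-East,20,18,C,A1:3
42,Silver Cr,L. melissa-East,6,6,Present,
43,Richfield,L. melissa-East,6,5,Present,A1:2
44,Victor,L. melissa-East,20,20,G,A1:11
45,Cokeville,L. melissa-East,10,10,G,A1:4
46,Montrose,L. melissa-East,20,20,G,A1:9;A16:1
47,De Beque,L. melissa-East,20,19,G,A1:5
48,Cimarron,L. melissa-East,6,6,Present,A1:1;A7:1
49,Goose Lk,L. melissa-East,20,20,G,A1:7
50,Montague,L. melissa-East,19,19,G,A1:17
51,Susanville,L. melissa-East,10,10,Present,A1:6
52,Abel Cr,L. melissa-East,19,19,C,A1:1
53,Deeth,L. melissa-East,20,20,G,A1:8
54,Mill Cr,L. melissa-East,24,24,Present,A1:14
55,East Cr CG,L. melissa-East,25,25,Present,A1:8
56,Lamoille,L. melissa-East,20,19,G,A1:10;B1:2
57,Ophir City,L. melissa-East,19,19,G,A1:8
58,Star Cr,L. melissa-East,16,16,G,A1:6
59,Upper Alkali,L. melissa-East,20,19,C,A1:6;A18:2
60,Surprise V,L. melissa-East,20,20,G,A1:13
61,Cody,L. melissa-Rockies,23,22,G,A1:11;A2:1
62,Lander,L. melissa-Rockies,24,23,G,A1:4
63,Wheatland,L. melissa-Rockies,16,16,Present,A1:9;A6:1;A19:2;I1:1
64,Yellow Pine CG,L. melissa-Rockies,20,20,G,A1:9;A2:1
65,Albion Meadow,L. melissa-Rockies,46,46,G,A2:40
66,Lake Davis,L. melissa-West,4,4,Present,A1:2
67,Sierravalley,L. melissa-West,20,20,Present,A1:2
68,White Lk,L. melissa-West,27,27,Present,A1:15;A6:4;A11:1;A19:1;B8:1;B44:1
69,Silver Lk,L. melissa-West,18,17,G,A1:5;B10:7
70,Girl Farm,L. melissa-West,24,24,Present,A1:3;A6:1;A11:2;B5:1;B7:1;B10:1;B18:1;B23:2;B24:1;B25:1;B26:1;B27:1;B28:1;D2:1;E1:1
71,Verdi Crystal,L. melissa-West,73,68,C,A1:14;A6:2;A11:1;A19:1;B5:2;B10:1;B23:1;B29:1;B30:2;B31:1;B32:1;B33:1;B34:1;H1:1
72,Verdi classic,L. melissa-West,26,25,Present,A1:2;A19:1;B5:1;B28:1;B35:1;B36:1;B37:1;B38:1;B39:1;B40:1
73,Verdi tracks,L. melissa-West,20,16,Present,B10:1;B11:1;B18:1;B22:1;B24:2;B33:1;B41:1;B42:1;B43:1;H2:1
74,Verdi hwy,L. melissa-West,11,11,Present,A1:1;A19:2;B23:1;B37:1
75,Qui,L. melissa-West,18,16,Present,A6:1;B2:1;B3:1;B4:2;B5:1;B6:1;B7:2;B8:1;B9:1;B10:1;B11:1
76,Deer Mt Road,L. melissa-West,27,23,Present,B4:2;B7:1;B12:1;B13:1;B14:1;B15:1;B16:1;B17:1;B18:1;B19:1;B20:1;B21:1;B22:1
77,Washoe Lk,L. melissa-West,20,18,G,A1:2;B10:1
78,Gardnerville,L. melissa-West,18,17,G,B10:6;F1:1
79,Red Earth,L. melissa-West,20,20,G,A1:8
80,Bishop,L. melissa-West,20,20,G,A1:11
81,Trout Pond,L. melissa-West,13,13,C,A1:4
82,Big Ice,Hybrid,18,18,G,A2:11
83,Blacktail Butte,Hybrid,46,45,G,A2:32
84,Bull Cr,Hybrid,46,45,G,A2:27
85,Dubois,Hybrid,41,41,G,A1:1;A2:29
86,Hunt Mt.,Hybrid,30,30,G,A2:24
87,Periodic Spr,Hybrid,20,20,G,A2:28
88,Pinnacles Butte,Hybrid,20,19,G,A2:17
89,Rendezvous Mt,Hybrid,32,32,G,A2:28
90,Riddle Lk,Hybrid,30,28,G,A2:22
91,Sheffield Cr,Hybrid,26,26,G,A2:22
92,Swift Cr,Hybrid,4,3,G,A2:2
93,Buck Mt,Hybrid,44,44,G,A2:28;A5:1
94,Eagle Pk,Hybrid,40,40,G,A2:32;A9:1
95,Steens Mt,Hybrid,13,11,G,A2:5
96,Hinkley,Hybrid,26,26,Present,A2:21;A13:1;A14:2
97,Jarbidge,Hybrid,42,40,Present,A2:30;A11:1;A13:5;A14:2;A15:1
98,Mt Rose,Hybrid,52,8,G,
99,Carson Pass,Hybrid,50,32,G,C1:20
100,Corey Pk,Hybrid,8,8,G,
101,Sonora Pass,Hybrid,44,33,G,C1:15
102,Lake Emma,Hybrid,33,17,G,C1:8
103,Sweetwater,Hybrid,23,13,G,C1:10
104,Tioga Crest,Hybrid,38,21,G,C1:5
105,South Fork,Hybrid,14,5,G,C1:5
106,County Line,Hybrid,40,35,G,B1:1;B10:6;C1:18;D1:1
107,Reed Flat,Hybrid,9,8,G,C1:4;C2:1
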