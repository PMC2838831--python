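sample_id	haplotype	mtdna_hg	y_hg	morph_sex	mol_sex	replicated
100	298-327	C4	-	Female	Female	yes
102	298-327	C4	-	Female	-
106	298-327	C4	R1a1a	Male	Male
107	223-298-309-327	C4	-	Female	-
109	298-327	C4	-	Female	-
110	298-327	C4	-	Female	-
111	223-298-309-327	C4	R1a1a	Male	Male
115	298-327	C4	R1a1a	Male	Male
117	223-304	M*	-	Female	Female
119	93-134-224-311-390	K	-	Female	Female	yes
120	189-192-311	R*	R1a1a	Male	Male
121	183-189-192-311	R*	R1a1a	Male	Male
127	223-298-309-327	C4	-	Female	Female	yes
128	260	H	-	Female	Female
131	189-192-311-390	R*	-	Female	Female
132	298-327	C4	-	Female	Female
135	223-298-309-327	C4	-	Female	Female
136	298-327	C4	R1a1a	Male	Male
138	298-327	C4	-	Female	-
139	298-327	C4	R1a1a	Male	Male
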