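person_id	role	sex	haplotype	flagged
E1	excavator	male	16189 16223 16278
E2	excavator	male	16093 16124 16223 16311 16316
E3	excavator	male	16223 16294 16362
E4	excavator	male	16223 16260 16298	*
E5	excavator	male	16092 16111 16261
E6	excavator	male	16300 16362
E7	excavator	female	16111 16129 16266 16304	*
E8	excavator	male	16221
E9	excavator	male	16126 16294 16296 16304
E10	excavator	male	16085 16209 16311
E11	excavator	male	16356
E12	excavator	male	16136 16356
L1	laboratory	female	16136 16183 16189 16217 16218 16239 16248	*
L2	laboratory	female	16223 16245 16362 16367
L3	laboratory	male	16183 16189 16223 16234 16290 16362
L4	laboratory	female	16126 16174 16223 16311 16362	*
L5	laboratory	male	16112 16223 16362
L6	laboratory	male	16213 16223 16298 16327
L7	laboratory	male	16189 16304
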