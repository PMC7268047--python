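subject,sex,age_years,lesion_side,lesion_location,lesion_volume_mm3,months_post_stroke,ue_fm,box_blocks_affected,box_blocks_unaffected
102,M,54,L,C/SC,187373,64,54,37,48
104,M,67,L,C/SC,113222,158,51,50,51
105,F,63,L,SC,3047,49,47,22,34
108,M,65,L,C/SC,67729,113,47,33,49
111,M,61,L,BS,188,41,26,13,42
114,M,40,R,CB/BS,23017,53,61,48,51
116,M,56,R,SC,14993,13,24,8,53
117,M,47,R,SC,3347,11,21,4,68
118,M,61,L,BS,199,12,52,44,55
120,M,57,L,SC,1635,6,36,28,46
121,F,53,R,C/SC,30003,13,43,23,31
124,F,67,R,SC,6170,22,28,2,43
125,F,60,R,SC,3691,7,59,44,48
126,F,35,L,BS,810,41,59,16,51
128,F,64,R,C/SC,16299,12,54,36,44
133,M,56,L,SC,1044,22,18,2,45
135,M,69,L,C/SC,105620,35,47,21,55
136,M,76,L,C/SC,30599,21,57,41,45
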