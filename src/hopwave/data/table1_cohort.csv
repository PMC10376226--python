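sex,group,age,index_limb,bmi,follow_up_years,tegner,kt1000_delta_mm,hop_ratio_pct
Male,ACLR,27,L,25,12,6,-1,94
Male,ACLR,29,L,33,12,3,3,85
Male,ACLR,30,L,29,12,9,-2,93
Male,ACLR,30,R,26,12,6,0,84
Male,ACLR,27,R,27,10,5,1,113
Female,ACLR,31,L,22,15,6,1,100
Female,ACLR,39,R,29,12,6,0,97
Female,ACLR,29,R,32,12,5,-2,85
Female,ACLR,36,R,20,12,7,0,104
Female,ACLR,60,L,26,12,4,-14,108
Female,ACLR,44,L,28,10,6,3,95
Male,Control,33,R,27,12,5,0,108
Male,Control,34,L,27,12,4,0,95
Male,Control,41,L,26,12,5,1,100
Male,Control,35,L,26,12,7,-1,95
Male,Control,31,R,20,10,6,-1,101
Male,Control,47,L,24,12,7,0,94
Male,Control,31,L,31,12,3,-1,111
Female,Control,43,L,21,12,6,1,96
Female,Control,38,R,26,10,6,0,106
Female,Control,49,R,23,15,6,0,91
Female,Control,45,R,21,12,6,-1,100
Female,Control,26,L,22,,4,0,91
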