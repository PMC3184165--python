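name,sequence,c_term_amide,precursor,range_start,range_end,note
Leu-Enk,YGGFL,false,Dyn B,1,5,literature-reported integer m/z 555 disagrees with computed [M+H]+ 556.28
Leu-Enk-Arg,YGGFLR,false,Dyn B,1,6,
Leu-Enk-Arg-Arg,YGGFLRR,false,Dyn B,1,7,literature-reported integer m/z 867 disagrees with computed [M+H]+ 868.48
aNeo(1-7),YGGFLRK,false,aNeo,1,7,
aNeo,YGGFLRKYPK,false,,,,
bNeo,YGGFLRKYP,false,aNeo,1,9,
Dyn A(1-8),YGGFLRRI,false,Dyn A(1-17),1,8,
Dyn A(1-17),YGGFLRRIRPKLKWDNQ,false,,,,literature-reported integer m/z 2145 disagrees with computed [M+H]+ 2147.20
Dyn A(10-17),PKLKWDNQ,false,Dyn A(1-17),10,17,
Dyn B,YGGFLRRQFKVVT,false,,,,
Substance P,RPKPQQFFGLM,true,,,,
Dyn A(2-8),GGFLRRI,false,Dyn A(1-17),2,8,des-Tyr metabolite
aNeo(2-10),GGFLRKYPK,false,aNeo,2,10,des-Tyr metabolite
Dyn B(2-13),GGFLRRQFKVVT,false,Dyn B,2,13,des-Tyr metabolite
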